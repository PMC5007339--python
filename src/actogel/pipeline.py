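"""End-to-end orchestration: simulate -> analyze -> fit -> report.

A :class:`RunConfig` lists scenarios (gel sweeps, gel-derived synthetic
analyses, Hill fits, agent-based runs); :func:`run_experiment` executes
them, writing CSV tables, a JSON manifest (config hash, seed, package
version) and a plain-text log, so a report bundle can be regenerated
bit-for-bit from its manifest.  :func:`compare_conditions` performs the
per-metric two-sample tests used when comparing activation-size or
crosslinking conditions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field as dc_field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .abm import ABMParams, boundary_speed, measure_strain, run as run_abm
from .contraction import contraction_summary
from .cooperativity import fit_hill
from .fields import ActivationRegion
from .gel import GelParameters, solve_gel, sweep_activation
from .io import save_table
from .synthetic import SynthConfig, gen_hill_dataset, gen_piv_series

__all__ = ["RunConfig", "run_experiment", "compare_conditions", "significance_stars"]

log = logging.getLogger("actogel")


@dataclass
class RunConfig:
    """Configuration of an experiment bundle.

    ``scenarios`` is a list of dicts, each with a ``kind`` key:
    ``gel_sweep`` (keys: xi_list, stiffness_list, gel params),
    ``gel_analysis`` (gel params + synth params: full closure run),
    ``hill`` (generator/fit params), ``abm`` (ABMParams overrides).
    """

    scenarios: list = dc_field(default_factory=list)
    outdir: str = "actogel_out"
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_gel_sweep(sc: dict, outdir: Path, seed: int) -> str:
    p = GelParameters(**sc.get("gel", {}))
    tab = sweep_activation(p, sc.get("xi_list", [5, 10, 20, 40]),
                           sc.get("stiffness_list", [1.0]))
    path = save_table(tab, outdir / "gel_sweep.csv", {"seed": seed})
    return str(path)


def _stage_gel_analysis(sc: dict, outdir: Path, seed: int) -> str:
    p = GelParameters(**sc.get("gel", {}))
    sol = solve_gel(p)
    cfg = SynthConfig(**{"seed": seed, **sc.get("synth", {})})
    series = gen_piv_series(cfg, sol)
    region = ActivationRegion((0.0, 0.0), p.xi)
    summary = contraction_summary(series, region)
    df = pd.DataFrame([summary.to_row()])
    df["seed"] = seed
    path = save_table(df, outdir / "gel_analysis.csv", {"seed": seed})
    return str(path)


def _stage_hill(sc: dict, outdir: Path, seed: int) -> str:
    df = gen_hill_dataset(**{"seed": seed, **sc.get("generator", {})})
    res = fit_hill(df["rho_per_um2"].values, df["epsilon_max"].values)
    out = pd.DataFrame(
        [
            {
                "eps_sat": res.eps_sat,
                "rho_half_per_um2": res.rho_half,
                "n_hill": res.n,
                "eps_sat_se": res.eps_sat_se,
                "rho_half_se": res.rho_half_se,
                "n_hill_se": res.n_se,
                "rss": res.rss,
                "converged": res.converged,
            }
        ]
    )
    path = save_table(out, outdir / "hill_fit.csv", {"seed": seed})
    return str(path)


def _stage_abm(sc: dict, outdir: Path, seed: int) -> str:
    p = ABMParams.reduced(**sc.get("abm", {})) if sc.get("reduced", True) else ABMParams(**sc.get("abm", {}))
    traj = run_abm(p, seed)
    tc = measure_strain(traj)
    _, vb = boundary_speed(traj)
    df = pd.DataFrame({"time_s": tc.times, "strain": tc.strain})
    df["mean_boundary_velocity_um_per_s"] = vb
    path = save_table(df, outdir / "abm_strain.csv", {"seed": seed})
    return str(path)


_STAGES = {
    "gel_sweep": _stage_gel_sweep,
    "gel_analysis": _stage_gel_analysis,
    "hill": _stage_hill,
    "abm": _stage_abm,
}


def run_experiment(config: RunConfig) -> dict:
    """Execute every scenario; returns (and writes) the manifest.

    Any stage failure aborts with an error naming the stage; partial
    outputs are retained next to a ``FAILED`` marker file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(outdir / "run.log")
    log.addHandler(fh)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "outputs": [],
    }
    try:
        for i, sc in enumerate(config.scenarios):
            kind = sc.get("kind")
            if kind not in _STAGES:
                raise ValueError(f"unknown scenario kind {kind!r}")
            log.info("stage %d: %s", i, kind)
            out = _STAGES[kind](sc, outdir, config.seed)
            manifest["outputs"].append({"stage": i, "kind": kind, "path": out})
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {kind!r} failed: {exc}\n")
        log.removeHandler(fh)
        raise RuntimeError(f"stage {kind!r} failed") from exc
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.removeHandler(fh)
    return manifest


def significance_stars(p: float) -> str:
    """Star convention: '***' for p < 0.001, '*' for p < 0.05, else 'ns'."""
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return "ns"


def compare_conditions(
    df: pd.DataFrame,
    group_col: str,
    metrics: list[str] | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Pairwise two-sample t-tests of every metric between condition groups.

    Welch's (unequal-variance) test by default, since replicate counts per
    condition typically differ; set ``equal_var=True`` for the pooled
    variant.  Requires at least 2 groups with at least 2 replicates each.
    """
    groups = {k: g for k, g in df.groupby(group_col)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    for k, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"group {k!r} has a single replicate; cannot test")
    if metrics is None:
        metrics = [c for c in df.columns if c != group_col and np.issubdtype(df[c].dtype, np.number)]
    rows = []
    for (a, b) in combinations(sorted(groups), 2):
        for m in metrics:
            t, p = stats.ttest_ind(
                groups[a][m], groups[b][m], equal_var=equal_var
            )
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "metric": m,
                    "t_stat": float(t),
                    "p_value": float(p),
                    "stars": significance_stars(float(p)),
                }
            )
    return pd.DataFrame(rows)
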