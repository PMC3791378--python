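"""Experiment orchestration: run condition grids, persist and report results.

``run_grid`` executes one simulation ensemble per condition (replicate r
uses seed ``base_seed + r``, so reruns are bit-reproducible and
conditions share common random numbers), writes one ensemble CSV per
condition plus a manifest recording the config hash and seeds.
``report`` turns ensemble files into the population statistics: notched
boxplot summaries, reach probabilities, crowding correlations and the
ANOVA/Tukey table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .genome import Genome
from .landscape import build_landscape
from .observables import (
    EnsembleResult,
    anova_tukey,
    boxplot_summary,
    crowding_correlation,
    first_passage_stats,
    occupancy_stats,
    reach_probability,
)
from .pwm import PWM
from .simulator import run_simulation
from .species import cognate_species, noncognate_species
from .synthetic import ExperimentCondition, generate_genome, generate_pwm

log = logging.getLogger("fdcrowd")


def build_condition_species(
    condition: ExperimentCondition, genome: Genome, pwm: PWM
):
    """Materialise the species list of one condition on a given genome."""
    landscape = build_landscape(pwm, genome, tau0=1e-5, beta=1.0)
    species = [
        cognate_species(
            condition.n_cognate, condition.k_assoc_cognate, landscape
        )
    ]
    if condition.n_nc > 0:
        species.append(
            noncognate_species(
                condition.n_nc,
                condition.k_assoc_nc,
                mobile=(condition.obstacle_mode == "mobile"),
            )
        )
    return species


def _config_hash(conditions: Sequence[ExperimentCondition]) -> str:
    payload = json.dumps([c.to_dict() for c in conditions], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _run_replicate(args):
    genome, species, duration, seed, stop, burn_in = args
    return run_simulation(
        genome,
        species,
        duration,
        seed,
        stop_at_first_passage=stop,
        coverage_burn_in=burn_in,
    )


def run_grid(
    conditions: Sequence[ExperimentCondition],
    genome: Genome,
    pwm: PWM,
    replicates: int,
    base_seed: int,
    *,
    stop_at_first_passage: bool = False,
    coverage_burn_in: float = 0.0,
    outdir: Optional[Path] = None,
    workers: int = 1,
) -> Dict[str, EnsembleResult]:
    """Run every condition for ``replicates`` independent replicates.

    Returns one :class:`EnsembleResult` per condition name; when
    ``outdir`` is given, also writes ``<condition>.csv`` files and a
    ``manifest.json`` with full provenance.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    results: Dict[str, EnsembleResult] = {}
    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(conditions),
        "base_seed": base_seed,
        "replicates": replicates,
        "stop_at_first_passage": stop_at_first_passage,
        "genome": genome.name,
        "conditions": {},
        "incomplete": [],
    }
    for cond in conditions:
        species = build_condition_species(cond, genome, pwm)
        jobs = [
            (genome, species, cond.duration, base_seed + r, stop_at_first_passage, coverage_burn_in)
            for r in range(replicates)
        ]
        if workers > 1:
            from joblib import Parallel, delayed

            trajectories = Parallel(n_jobs=workers)(
                delayed(_run_replicate)(j) for j in jobs
            )
        else:
            trajectories = [_run_replicate(j) for j in jobs]
        records = []
        for r, traj in enumerate(trajectories):
            records.append(
                {
                    "replicate": r,
                    "seed": base_seed + r,
                    "condition": cond.name,
                    "crowding": cond.crowding,
                    "first_passage": traj.first_passage,
                    "censored": traj.censored,
                    "occupancy_fraction": traj.occupancy_fraction,
                    "mean_coverage": traj.mean_coverage,
                }
            )
            log.info("condition %s replicate %d/%d done", cond.name, r + 1, replicates)
        ens = EnsembleResult.from_records(records)
        results[cond.name] = ens
        manifest["conditions"][cond.name] = {
            "seeds": [base_seed + r for r in range(replicates)],
            "crowding": cond.crowding,
            "file": f"{cond.name}.csv",
        }
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            ens.to_csv(outdir / f"{cond.name}.csv")
    if outdir is not None:
        (Path(outdir) / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


def report(
    ensembles: Dict[str, EnsembleResult],
    *,
    outdir: Optional[Path] = None,
    alpha: float = 0.05,
    make_figures: bool = False,
) -> dict:
    """Condition-level statistics across one or more ensembles.

    Produces per-condition first-passage/occupancy boxplot summaries and
    reach probabilities, crowding correlations across conditions (when at
    least three distinct crowding levels are present), and the one-way
    ANOVA with Tukey's range test on first-passage times.
    """
    if len(ensembles) == 0:
        raise ValueError("need at least one ensemble")
    per_condition = {}
    crowding_levels, fp_means, occ_means = [], [], []
    fp_groups = {}
    for name, ens in ensembles.items():
        df = ens.data
        entry: dict = {
            "n": int(len(df)),
            "crowding": float(df["crowding"].iloc[0]),
            "reach_probability": reach_probability(ens),
        }
        uncensored = df.loc[~df["censored"].astype(bool), "first_passage"]
        if len(uncensored) >= 1:
            entry["first_passage"] = first_passage_stats(ens)
            entry["first_passage_box"] = boxplot_summary(uncensored.to_numpy(float)).__dict__
            if len(uncensored) >= 2:
                fp_groups[name] = uncensored.to_numpy(float)
        entry["occupancy"] = occupancy_stats(ens)
        entry["occupancy_box"] = boxplot_summary(
            df["occupancy_fraction"].to_numpy(float)
        ).__dict__
        per_condition[name] = entry
        crowding_levels.append(entry["crowding"])
        fp_means.append(entry.get("first_passage", {}).get("mean", np.nan))
        occ_means.append(entry["occupancy"]["mean"])

    out = {"per_condition": per_condition}
    distinct = len(set(crowding_levels))
    if distinct >= 3:
        fp = np.asarray(fp_means)
        ok = ~np.isnan(fp)
        if ok.sum() >= 3 and np.ptp(np.asarray(crowding_levels)[ok]) > 0:
            out["crowding_vs_search_time_r"] = crowding_correlation(
                np.asarray(crowding_levels)[ok], fp[ok]
            )
        if np.ptp(crowding_levels) > 0 and np.ptp(occ_means) > 0:
            out["crowding_vs_occupancy_r"] = crowding_correlation(
                crowding_levels, occ_means
            )
    if len(fp_groups) >= 2:
        res = anova_tukey(fp_groups, alpha=alpha)
        out["anova"] = {"F": res.f_statistic, "p": res.p_value}
        out["tukey"] = [p.__dict__ for p in res.pairs]

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(out, indent=2, default=float))
        rows = [
            {"condition": name, "crowding": e["crowding"], "n": e["n"],
             "reach_probability": e["reach_probability"],
             "mean_first_passage": e.get("first_passage", {}).get("mean"),
             "mean_occupancy": e["occupancy"]["mean"],
             "var_occupancy": e["occupancy"]["variance"]}
            for name, e in per_condition.items()
        ]
        pd.DataFrame(rows).to_csv(outdir / "summary.csv", index=False)
        if make_figures:
            _write_figures(ensembles, outdir)
    return out


def _write_figures(ensembles: Dict[str, EnsembleResult], outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for quantity, col in [("first_passage", "first_passage"), ("occupancy", "occupancy_fraction")]:
        fig, ax = plt.subplots(figsize=(6, 4))
        labels, samples = [], []
        for name, ens in ensembles.items():
            df = ens.data
            vals = (
                df.loc[~df["censored"].astype(bool), col]
                if col == "first_passage"
                else df[col]
            ).dropna().to_numpy(float)
            if len(vals) > 0:
                labels.append(f"{df['crowding'].iloc[0]:.0%}")
                samples.append(vals)
        if samples:
            ax.boxplot(samples, notch=True, tick_labels=labels, sym="+")
            ax.set_xlabel("DNA crowding")
            ax.set_ylabel("search time (s)" if col == "first_passage" else "occupancy fraction")
            fig.tight_layout()
            fig.savefig(outdir / f"{quantity}_boxplot.svg")
        plt.close(fig)
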