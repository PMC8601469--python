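"""Density-sweep driver: simulate, analyse and classify a (phi1, phi2) grid."""

from __future__ import annotations

import logging
from typing import Callable, Optional

import pandas as pd

from .config import RunConfig
from .dynamics import simulate
from .lattice import generate_lattice
from .patterns import classify_pattern
from .stats import summarize

__all__ = ["run_survey"]

log = logging.getLogger("dictywaves")


def run_survey(
    config: RunConfig,
    classify: bool = True,
    progress: Optional[Callable[[str], None]] = None,
) -> pd.DataFrame:
    """Run the full (phi1, phi2, replicate) grid of the survey block.

    Each entry of the survey's seed list is one replicate (the convention is
    consecutive seeds ``base, base+1, ...`` so replicates stay auditable);
    every cell generates its own lattice from its seed, simulates, and
    tabulates one tidy row: the synchrony index S, the time-averaged mean
    field, the log-sigma growth slope, the crossover time T and the advisory
    pattern label.  A failing cell is logged and reported with its error
    message; it never aborts the remaining sweep.
    """
    if not config.survey.phi1 or not config.survey.phi2:
        raise ValueError("survey needs non-empty phi1 and phi2 lists")
    if not config.survey.seeds:
        raise ValueError("survey needs at least one replicate seed")

    rows = []
    for phi1 in config.survey.phi1:
        for phi2 in config.survey.phi2:
            for seed in config.survey.seeds:
                seed = int(seed)
                row = {"phi1": phi1, "phi2": phi2, "seed": seed, "error": ""}
                try:
                    lattice = generate_lattice(config.lattice.N, phi1, phi2, seed)
                    traj = simulate(
                        lattice,
                        config.params,
                        n_iter=config.run.n_iter,
                        record_every=config.run.record_every,
                        seed=seed,
                        record_fields=classify,
                        f_fire=config.lattice.f_fire,
                        u_fire=config.lattice.u_fire,
                    )
                    summary = summarize(traj)
                    row.update(
                        S=summary["S"],
                        ubar_mean=summary["ubar_mean"],
                        growth_slope=summary["growth_slope"],
                        crossover_T=summary["crossover_T"],
                    )
                    if classify:
                        row["label"] = classify_pattern(traj).label
                except Exception as err:  # noqa: BLE001 - isolate per-cell failures
                    log.warning(
                        "survey cell phi1=%s phi2=%s seed=%s failed: %s",
                        phi1, phi2, seed, err,
                    )
                    row["error"] = str(err)
                rows.append(row)
                if progress is not None:
                    progress(f"phi1={phi1} phi2={phi2} seed={seed} done")
    return pd.DataFrame(rows)
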