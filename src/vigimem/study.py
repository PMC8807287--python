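"""End-to-end cohort analysis: the :class:`CohortStudy` model and its
:class:`StudyResults`.

``CohortStudy`` is built from the four cohort tables (participant metadata,
vigilance trials, block ratings, memory probes); ``fit()`` runs scoring ->
decrement statistics -> parametric and resampling endpoints -> time-binned
and correlation analyses -> Bonferroni adjustment over the battery
endpoints, and returns a ``StudyResults`` carrying every estimate with its
uncertainty, a ``summary()`` table renderer, and JSON serialization.  The
whole pipeline is deterministic given (tables, options, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__ as _version
from .memory import participant_memory_summary, residualize_on_interval
from .parametric import (
    TTestResult,
    bonferroni,
    partial_spearman,
    pca_composite,
    round_printed,
    spearman,
    two_sample_t,
)
from .resampling import InferenceError, ResamplingResult, bootstrap_group_test, bootstrap_timeseries
from .vigilance import f1_timeseries, participant_vigilance_summary, score_blocks

__all__ = ["CohortStudy", "StudyResults", "bin_by_time_since_diagnosis"]

logger = logging.getLogger("vigimem")

DAYS_PER_MONTH = 30.44

# vigilance endpoints compared between groups, label -> summary column
VIGILANCE_ENDPOINTS = {
    "baseline_accuracy": "baseline_accuracy",
    "final_accuracy": "final_accuracy",
    "overall_accuracy": "overall_accuracy",
    "absolute_change": "absolute_change",
    "vigilance_decrement": "vigilance_decrement",
    "rt_change_normalized": "rt_change_normalized",
    "fatigue_baseline": "fatigue_baseline",
    "fatigue_change": "fatigue_change",
    "motivation_baseline": "motivation_baseline",
    "motivation_change": "motivation_change",
}
MEMORY_ENDPOINTS = {
    "memory_immediate_accuracy": "immediate_accuracy",
    "memory_delayed_accuracy": "delayed_accuracy",
    "memory_decrement": "memory_decrement",
    "orientation_fa_immediate": "orientation_fa_immediate",
    "orientation_fa_delayed": "orientation_fa_delayed",
    "word_memory_decrement": "word_memory_decrement",
    "maintenance_interval": "maintenance_interval",
}
# endpoints counted as the cognitive-battery family for Bonferroni
BATTERY_ENDPOINTS = list(MEMORY_ENDPOINTS)


def bin_by_time_since_diagnosis(
    exposed: pd.DataFrame,
    control_values: np.ndarray,
    value_col: str,
    edges_months: Tuple[float, ...] = (2.0, 9.0),
    n_iter: int = 10_000,
    seed: int = 0,
) -> List[dict]:
    """Bin exposed participants by months since diagnosis and compare each
    bin against controls with the bootstrap group test.

    ``exposed`` needs ``days_since_diagnosis`` and ``value_col`` columns;
    months = days / 30.44.  Empty bins are reported as empty, not errors.
    """
    months = exposed["days_since_diagnosis"].to_numpy(dtype=float) / DAYS_PER_MONTH
    values = exposed[value_col].to_numpy(dtype=float)
    bounds = [0.0, *edges_months, np.inf]
    control = np.asarray(control_values, dtype=float)
    control = control[~np.isnan(control)]
    out = []
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        label = f"{lo:g}-{hi:g}m" if np.isfinite(hi) else f">{lo:g}m"
        sel = (months >= lo) & (months < hi) & ~np.isnan(values)
        vals = values[sel]
        entry = {
            "bin": label,
            "lo_months": lo,
            "hi_months": hi if np.isfinite(hi) else None,
            "n": int(vals.size),
        }
        if vals.size == 0:
            entry.update(mean=None, se=None, bootstrap_p=None, sign_significant=None)
        else:
            entry["mean"] = float(vals.mean())
            entry["se"] = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else None
            if vals.size >= 2 and control.size >= 2:
                res = bootstrap_group_test(
                    vals, control, n_iter=n_iter, seed=seed + i
                )
                entry["bootstrap_p"] = float(res.p_value)
                entry["sign_significant"] = bool(res.significance_mask)
            else:
                entry["bootstrap_p"] = None
                entry["sign_significant"] = None
        out.append(entry)
    return out


def _fmt_t(res: TTestResult) -> str:
    return (
        f"t({res.df:g}) = {round_printed(res.t):g}, P = {res.p:.3g}, "
        f"BF10 = {res.bf10:.3g}"
    )


@dataclass
class StudyResults:
    """Fitted study endpoints; see :meth:`summary` and :meth:`to_dict`."""

    groups: Tuple[str, str]
    vigilance: pd.DataFrame
    memory: Optional[pd.DataFrame]
    group_tests: Dict[str, TTestResult]
    group_summaries: Dict[str, dict]
    bootstrap_tests: Dict[str, ResamplingResult]
    timeseries: Optional[ResamplingResult]
    correlations: Dict[str, dict]
    time_bins: Dict[str, List[dict]]
    composite: Optional[dict]
    bonferroni_table: Optional[pd.DataFrame]
    skipped: List[Tuple[str, str]]
    provenance: dict

    def to_dict(self) -> dict:
        d = {
            "groups": list(self.groups),
            "provenance": self.provenance,
            "group_summaries": self.group_summaries,
            "group_tests": {k: v.to_dict() for k, v in self.group_tests.items()},
            "bootstrap_tests": {k: v.to_dict() for k, v in self.bootstrap_tests.items()},
            "correlations": self.correlations,
            "time_bins": self.time_bins,
            "skipped": [list(s) for s in self.skipped],
        }
        if self.timeseries is not None:
            d["timeseries"] = self.timeseries.to_dict()
        if self.composite is not None:
            d["composite"] = self.composite
        if self.bonferroni_table is not None:
            d["bonferroni"] = self.bonferroni_table.to_dict(orient="records")
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def summary(self) -> str:
        """Human-readable endpoint tables; every number is a formatted copy
        of a ``to_dict`` field."""
        ga, gb = self.groups
        lines = [
            f"Cohort analysis: {ga} (n={self.provenance['n_group_a']}) vs "
            f"{gb} (n={self.provenance['n_group_b']})",
            f"seed={self.provenance['seed']}  n_iter={self.provenance['n_iter']}  "
            f"vigimem {self.provenance['version']}",
            "",
            f"{'endpoint':<28}{ga + ' mean (SD)':>20}{gb + ' mean (SD)':>20}  statistic",
        ]
        for name, test in self.group_tests.items():
            ma, sa, na = test.summary_a
            mb, sb, nb = test.summary_b
            lines.append(
                f"{name:<28}{f'{ma:.1f} ({sa:.1f})':>20}{f'{mb:.1f} ({sb:.1f})':>20}"
                f"  {_fmt_t(test)}"
            )
        if self.bootstrap_tests:
            lines.append("")
            lines.append("bootstrap group tests (resample N = smaller group):")
            for name, res in self.bootstrap_tests.items():
                lines.append(
                    f"  {name}: two-sided p = {float(res.p_value):.4g}; "
                    f"sign criterion (>95% one side, the trial-faithful rule): "
                    f"{'significant' if bool(res.significance_mask) else 'n.s.'}"
                )
        if self.timeseries is not None:
            mask = np.asarray(self.timeseries.significance_mask)
            sig_blocks = np.flatnonzero(mask)
            lines.append("")
            lines.append(
                "minute-wise bootstrap divergence mask (block indices, 0 = practice): "
                + (", ".join(map(str, sig_blocks)) if sig_blocks.size else "none")
            )
        for name, corr in self.correlations.items():
            lines.append(f"correlation {name}: rho = {corr['rho']:.2f}, P = {corr['p']:.3g}")
        for name, bins in self.time_bins.items():
            lines.append(f"time bins ({name}):")
            for b in bins:
                if b["n"] == 0:
                    lines.append(f"  {b['bin']}: empty")
                else:
                    p = b["bootstrap_p"]
                    lines.append(
                        f"  {b['bin']}: n={b['n']}, mean={b['mean']:.1f}"
                        + (f", bootstrap p={p:.4g}" if p is not None else "")
                    )
        if self.bonferroni_table is not None and len(self.bonferroni_table):
            lines.append("")
            lines.append(f"Bonferroni family (m={self.provenance['bonferroni_m']}):")
            for _, row in self.bonferroni_table.iterrows():
                lines.append(
                    f"  {row['endpoint']}: p = {row['p']:.4g} -> adjusted {row['p_adjusted']:.4g}"
                )
        for name, reason in self.skipped:
            lines.append(f"skipped {name}: {reason}")
        return "\n".join(lines)


class CohortStudy:
    """Two-group vigilance + memory cohort, ready to fit.

    Parameters
    ----------
    participants, trials : DataFrame
        Required metadata and vigilance trial tables (layouts in
        :mod:`vigimem.io`).
    ratings, memory : DataFrame, optional
        Block ratings and memory probes; endpoints that need an absent table
        are skipped with a logged reason.
    """

    def __init__(
        self,
        participants: pd.DataFrame,
        trials: pd.DataFrame,
        ratings: Optional[pd.DataFrame] = None,
        memory: Optional[pd.DataFrame] = None,
    ):
        self.participants = participants
        self.trials = trials
        self.ratings = ratings
        self.memory = memory
        groups = list(dict.fromkeys(participants["group"]))
        if "days_since_diagnosis" in participants.columns:
            has_days = (
                participants.groupby("group", sort=False)["days_since_diagnosis"]
                .apply(lambda s: s.notna().any())
            )
            exposed = [g for g in groups if has_days.get(g, False)]
            if len(exposed) == 1 and len(groups) == 2:
                groups = [exposed[0]] + [g for g in groups if g != exposed[0]]
        self.groups = groups

    @classmethod
    def from_csv(cls, data_dir) -> "CohortStudy":
        from .io import read_tables

        tables = read_tables(data_dir)
        return cls(
            tables["participants"],
            tables["trials"],
            ratings=tables["ratings"],
            memory=tables["memory"],
        )

    # ------------------------------------------------------------------
    def _group_values(self, summary: pd.DataFrame, col: str, group: str) -> np.ndarray:
        merged = summary.merge(
            self.participants[["participant_id", "group"]], on="participant_id"
        )
        vals = merged.loc[merged["group"] == group, col].to_numpy(dtype=float)
        return vals[~np.isnan(vals)]

    def fit(
        self,
        n_iter: int = 10_000,
        alpha: float = 0.05,
        seed: int = 0,
        bonferroni_m: int = 29,
        vigilance_bin_edges_months: Tuple[float, ...] = (2.0, 9.0),
        memory_bin_edges_months: Tuple[float, ...] = (6.0,),
        adjust_maintenance_interval: bool = False,
    ) -> StudyResults:
        """Run the full analysis; deterministic given the inputs and seed."""
        rng_seeds = np.random.SeedSequence(seed).generate_state(8).tolist()

        block_scores = score_blocks(self.trials)
        logger.info("scored %d participant-blocks", len(block_scores))
        vig = participant_vigilance_summary(block_scores, self.ratings)
        logger.info("vigilance summaries: %d participants", len(vig))
        mem = (
            participant_memory_summary(self.memory, self.participants)
            if self.memory is not None
            else None
        )
        if mem is not None:
            logger.info("memory summaries: %d participants", len(mem))
            if adjust_maintenance_interval and "maintenance_interval" in mem.columns:
                mem = mem.copy()
                mem["memory_decrement"] = residualize_on_interval(
                    mem["memory_decrement"].to_numpy(),
                    mem["maintenance_interval"].to_numpy(),
                )

        single_group = len(self.groups) < 2
        group_tests: Dict[str, TTestResult] = {}
        group_summaries: Dict[str, dict] = {g: {} for g in self.groups}
        skipped: List[Tuple[str, str]] = []

        def run_endpoints(summary_df: pd.DataFrame, endpoints: Dict[str, str]) -> None:
            for label, col in endpoints.items():
                if col not in summary_df.columns:
                    skipped.append((label, "column absent from input tables"))
                    continue
                per_group = {
                    g: self._group_values(summary_df, col, g) for g in self.groups
                }
                for g, vals in per_group.items():
                    if vals.size:
                        group_summaries[g][label] = {
                            "mean": float(vals.mean()),
                            "sd": float(vals.std(ddof=1)) if vals.size > 1 else None,
                            "n": int(vals.size),
                        }
                if single_group:
                    continue
                a, b = per_group[self.groups[0]], per_group[self.groups[1]]
                if a.size < 2 or b.size < 2:
                    skipped.append((label, f"insufficient n ({a.size} vs {b.size})"))
                    continue
                group_tests[label] = two_sample_t(a, b)

        run_endpoints(vig, VIGILANCE_ENDPOINTS)
        if mem is not None and len(mem):
            run_endpoints(mem, MEMORY_ENDPOINTS)
        elif self.memory is None:
            skipped.append(("memory_endpoints", "no memory probe table supplied"))

        bootstrap_tests: Dict[str, ResamplingResult] = {}
        timeseries = None
        correlations: Dict[str, dict] = {}
        time_bins: Dict[str, List[dict]] = {}
        composite = None
        bonf_table = None

        if not single_group:
            ga, gb = self.groups[0], self.groups[1]
            # resampling endpoints
            for i, (label, summary_df, col) in enumerate(
                [
                    ("vigilance_decrement", vig, "vigilance_decrement"),
                    ("memory_decrement", mem, "memory_decrement"),
                ]
            ):
                if summary_df is None or col not in getattr(summary_df, "columns", []):
                    continue
                a = self._group_values(summary_df, col, ga)
                b = self._group_values(summary_df, col, gb)
                if a.size < 2 or b.size < 2:
                    skipped.append((f"bootstrap_{label}", "insufficient n"))
                    continue
                bootstrap_tests[label] = bootstrap_group_test(
                    a, b, n_iter=n_iter, alpha=alpha, seed=int(rng_seeds[i])
                )

            # minute-wise divergence
            ts = f1_timeseries(block_scores).merge(
                self.participants.set_index("participant_id")[["group"]],
                left_index=True,
                right_index=True,
            )
            mat_a = ts.loc[ts["group"] == ga].drop(columns="group").to_numpy(dtype=float)
            mat_b = ts.loc[ts["group"] == gb].drop(columns="group").to_numpy(dtype=float)
            complete_a = mat_a[~np.isnan(mat_a).any(axis=1)]
            complete_b = mat_b[~np.isnan(mat_b).any(axis=1)]
            if complete_a.shape[0] >= 2 and complete_b.shape[0] >= 2:
                timeseries = bootstrap_timeseries(
                    complete_a,
                    complete_b,
                    n_iter=n_iter,
                    alpha=alpha,
                    seed=int(rng_seeds[2]),
                )
                logger.info(
                    "timeseries bootstrap: %d vs %d complete trajectories",
                    complete_a.shape[0],
                    complete_b.shape[0],
                )
            else:
                skipped.append(("timeseries", "insufficient complete trajectories"))

            # correlations with time since diagnosis (exposed group only)
            exposed_meta = self.participants[self.participants["group"] == ga]
            for label, summary_df, col in [
                ("vigilance_decrement_vs_days", vig, "vigilance_decrement"),
                ("memory_decrement_vs_days", mem, "memory_decrement"),
            ]:
                if summary_df is None or col not in getattr(summary_df, "columns", []):
                    continue
                merged = exposed_meta.merge(summary_df, on="participant_id")
                days = merged["days_since_diagnosis"].to_numpy(dtype=float)
                vals = merged[col].to_numpy(dtype=float)
                ok = ~(np.isnan(days) | np.isnan(vals))
                if ok.sum() < 5:
                    skipped.append((label, "too few exposed participants with dates"))
                    continue
                rho, p = spearman(days[ok], vals[ok])
                correlations[label] = {"rho": rho, "p": p, "n": int(ok.sum())}
                covs = []
                if "age" in merged.columns:
                    covs.append(merged["age"].to_numpy(dtype=float))
                if "grit" in merged.columns:
                    covs.append(merged["grit"].to_numpy(dtype=float))
                if covs:
                    Z = np.column_stack(covs)
                    ok2 = ok & ~np.isnan(Z).any(axis=1)
                    if ok2.sum() >= 8:
                        prho, pp = partial_spearman(days[ok2], vals[ok2], Z[ok2])
                        correlations[label + "_partial"] = {
                            "rho": prho,
                            "p": pp,
                            "n": int(ok2.sum()),
                            "covariates": ["age", "grit"][: Z.shape[1]],
                        }

                # time-binned comparisons against controls
                edges = (
                    vigilance_bin_edges_months
                    if col == "vigilance_decrement"
                    else memory_bin_edges_months
                )
                control_vals = self._group_values(summary_df, col, gb)
                if ok.sum() >= 2 and control_vals.size >= 2:
                    time_bins[col] = bin_by_time_since_diagnosis(
                        merged.loc[ok],
                        control_vals,
                        col,
                        edges_months=edges,
                        n_iter=n_iter,
                        seed=int(rng_seeds[3]),
                    )

            # composite memory score (first PC of available accuracy measures)
            if mem is not None and len(mem):
                comp_cols = [
                    c
                    for c in ("immediate_accuracy", "word_immediate_accuracy")
                    if c in mem.columns
                ]
                comp_df = mem[["participant_id", *comp_cols]].dropna()
                if len(comp_cols) >= 2 and len(comp_df) >= 4:
                    cs = pca_composite(comp_df[comp_cols])
                    scores = pd.DataFrame(
                        {"participant_id": comp_df["participant_id"], "score": cs.scores}
                    )
                    a = self._group_values(scores, "score", ga)
                    b = self._group_values(scores, "score", gb)
                    composite = {
                        "measures": comp_cols,
                        "loadings": cs.loadings.to_dict(),
                        "variance_explained": cs.variance_explained,
                    }
                    if a.size >= 2 and b.size >= 2:
                        group_tests["short_term_memory_composite"] = two_sample_t(a, b)

            # Bonferroni over the battery family
            battery = {
                k: v for k, v in group_tests.items() if k in BATTERY_ENDPOINTS
            }
            if battery:
                names = list(battery)
                ps = np.array([battery[k].p for k in names])
                adj = bonferroni(ps, max(bonferroni_m, ps.size))
                bonf_table = pd.DataFrame(
                    {"endpoint": names, "p": ps, "p_adjusted": adj}
                )
        else:
            skipped.append(("group_comparisons", "single group: between-group endpoints skipped"))

        for label, reason in skipped:
            logger.info("skipped %s: %s", label, reason)

        n_by_group = self.participants["group"].value_counts()
        provenance = {
            "seed": seed,
            "n_iter": n_iter,
            "alpha": alpha,
            "bonferroni_m": bonferroni_m,
            "version": _version,
            "n_group_a": int(n_by_group.get(self.groups[0], 0)),
            "n_group_b": int(n_by_group.get(self.groups[1], 0)) if not single_group else 0,
            "component_seeds": [int(s) for s in rng_seeds],
        }
        return StudyResults(
            groups=tuple(self.groups[:2]) if not single_group else (self.groups[0], ""),
            vigilance=vig,
            memory=mem,
            group_tests=group_tests,
            group_summaries=group_summaries,
            bootstrap_tests=bootstrap_tests,
            timeseries=timeseries,
            correlations=correlations,
            time_bins=time_bins,
            composite=composite,
            bonferroni_table=bonf_table,
            skipped=skipped,
            provenance=provenance,
        )
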