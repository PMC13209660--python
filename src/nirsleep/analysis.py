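"""ROI-based and channel-wise sleep-stage analyses and the pipeline driver.

The ROI-based route averages windowed mean responses over fixed channel
lists (derived from full-cohort activation maps in prior work and shipped
here as a registry), applies the per-group 1.5*IQR outlier rule, and
compares AS vs QS with the full test battery (t, permutation p, Cohen's d,
bootstrap CI). The channel-wise route tests each of the 18 channels against
baseline (one-sample t, BH-FDR across the 18-channel family per
chromophore), then tests condition contrasts (paired t) only on the
channels significant against baseline, and converts the outcomes into
activation calls: HbO increases and/or HbR decreases count as activation,
while both chromophores moving in the same direction is atypical and
excluded from interpretation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import preprocess as pp
from .allocation import (
    AllocationResult,
    allocate_hand,
    allocate_social,
    build_analysis_groups,
    label_trials,
)
from .staging import assess_codability, default_coding_scheme, derive_timeline
from .stats import (
    StatsParams,
    TestResult,
    bh_fdr,
    bootstrap_d_ci,
    cohens_d_pooled,
    compare_groups,
    iqr_filter,
    location_test,
    permutation_test,
    sign_flip_test,
)
from .synthetic import CohortConfig, generate_cohort, hand_paradigm, social_paradigm

logger = logging.getLogger("nirsleep")

__all__ = [
    "ROIDefinition",
    "ActivationCall",
    "ROI_REGISTRY",
    "roi_mean",
    "roi_group_comparison",
    "channelwise_analysis",
    "data_quality_table",
    "run_pipeline",
]

CHROMOPHORES = ("HbO", "HbR")


@dataclass(frozen=True)
class ROIDefinition:
    cohort: str
    analysis: str
    channels: Mapping[str, tuple[int, ...]]  # chromophore -> channel ids

    def __post_init__(self) -> None:
        for chrom, ids in self.channels.items():
            if not set(ids) <= set(range(1, 19)):
                raise ValueError(f"{chrom} channel ids must lie in 1..18")


# Channel lists from the full-cohort activation and contrast maps that the
# sleep-stage analyses inherit (per cohort and analysis).
ROI_REGISTRY: dict[tuple[str, str], ROIDefinition] = {
    (c, a): ROIDefinition(c, a, ch)
    for (c, a), ch in {
        ("UK", "social_activation"): {"HbO": (9, 15, 16, 18), "HbR": (15, 18)},
        ("GM", "social_activation"): {
            "HbO": (15, 16, 18),
            "HbR": (6, 7, 9, 10, 13, 15, 16, 18),
        },
        ("UK", "fam1_activation"): {"HbO": (4, 7), "HbR": (7, 15, 18)},
        ("GM", "fam1_activation"): {"HbO": (1, 4, 7, 13), "HbR": (4, 7, 13)},
        ("UK", "nv_contrast"): {
            "HbO": (4, 13, 14, 15, 16),
            "HbR": (4, 7, 9, 13, 14, 15, 16, 17, 18),
        },
        ("UK", "habituation"): {"HbO": (4, 7), "HbR": (7,)},
        ("GM", "habituation"): {"HbO": (1, 7), "HbR": (4, 7, 13)},
    }.items()
}


@dataclass
class ActivationCall:
    channel: int
    chromophore: str
    direction: int  # sign of the mean response
    activated: bool
    atypical: bool = False


def roi_mean(
    responses: pd.DataFrame,
    roi: ROIDefinition,
    condition: str,
    chromophore: str,
) -> pd.Series:
    """Per-subject mean of the windowed responses over the ROI channels.

    ``responses`` is tidy: columns subject_id, channel, chromophore,
    condition, value.
    """
    channels = roi.channels.get(chromophore, ())
    if not channels:
        raise KeyError(f"ROI has no {chromophore} channels")
    sel = responses[
        (responses["condition"] == condition)
        & (responses["chromophore"] == chromophore)
        & (responses["channel"].isin(channels))
    ]
    present = set(sel["channel"].unique())
    if present != set(channels):
        raise KeyError(f"missing ROI channels {sorted(set(channels) - present)}")
    return sel.groupby("subject_id")["value"].mean()


def roi_group_comparison(
    qs_values,
    as_values,
    params: StatsParams | None = None,
    variant: str = "pooled",
) -> TestResult:
    """AS-vs-QS comparison of per-subject ROI amplitudes or contrasts.

    The 1.5*IQR rule is applied within each sleep-stage group first; the
    statistic is computed as AS minus QS (negative t = smaller in AS).
    Pooled-variance t is the default for these comparisons; Welch is
    available via ``variant``.
    """
    params = params or StatsParams()
    qs = np.asarray(qs_values, dtype=float)
    as_ = np.asarray(as_values, dtype=float)
    qs_f, _ = iqr_filter(qs, params.iqr_multiplier)
    as_f, _ = iqr_filter(as_, params.iqr_multiplier)
    if qs_f.size < 2 or as_f.size < 2:
        raise ValueError("fewer than two observations per group after filtering")
    res = compare_groups(as_f, qs_f, params=params, variant=variant)
    res.extra["n_removed"] = {"QS": int(qs.size - qs_f.size),
                              "AS": int(as_.size - as_f.size)}
    return res


def channelwise_analysis(
    responses: pd.DataFrame,
    condition: str,
    comparison_condition: str | None = None,
    params: StatsParams | None = None,
    contrast_family: str = "significant",
) -> tuple[list[ActivationCall], pd.DataFrame]:
    """Two-stage channel-wise testing within one sleep-stage group.

    Stage 1: per chromophore, one-sample t tests of the 18 channels'
    responses against baseline (0), BH-FDR across the 18-channel family.
    Stage 2 (when ``comparison_condition`` is given): paired t tests of
    condition vs comparison condition, run only on the channels significant
    in stage 1, BH-FDR across that significant set (``contrast_family`` can
    be set to "all" to correct across all 18 channels instead).

    Returns activation calls and a tidy per-channel result table.
    """
    params = params or StatsParams()
    rows = []
    sig_by_chrom: dict[str, list[int]] = {}
    mean_sign: dict[tuple[int, str], int] = {}
    sig_lookup: dict[tuple[int, str], bool] = {}
    for chrom in CHROMOPHORES:
        pvals, channels, stats_ = [], [], []
        for ch in range(1, 19):
            x = responses[
                (responses["condition"] == condition)
                & (responses["chromophore"] == chrom)
                & (responses["channel"] == ch)
            ].sort_values("subject_id")["value"].to_numpy()
            if x.size < 3:
                raise ValueError("channel-wise tests need at least 3 subjects")
            res = location_test(x, mode="one_sample")
            p_perm = sign_flip_test(x, params)
            pvals.append(res.p_parametric)
            channels.append(ch)
            stats_.append((res, p_perm, float(x.mean())))
        p_adj, sig = bh_fdr(pvals, params.alpha)
        sig_by_chrom[chrom] = [c for c, s in zip(channels, sig) if s]
        for ch, (res, p_perm, m), padj, s in zip(channels, stats_, p_adj, sig):
            mean_sign[(ch, chrom)] = int(np.sign(m)) or 1
            sig_lookup[(ch, chrom)] = bool(s)
            rows.append(
                {
                    "stage": "activation",
                    "channel": ch,
                    "chromophore": chrom,
                    "t": res.statistic,
                    "df": res.df,
                    "p": res.p_parametric,
                    "p_adj": float(padj),
                    "p_permutation": p_perm,
                    "mean": m,
                    "significant": bool(s),
                }
            )

    calls = []
    for ch in range(1, 19):
        hbo_sig = sig_lookup[(ch, "HbO")]
        hbr_sig = sig_lookup[(ch, "HbR")]
        hbo_dir = mean_sign[(ch, "HbO")]
        hbr_dir = mean_sign[(ch, "HbR")]
        atypical = hbo_sig and hbr_sig and hbo_dir == hbr_dir
        for chrom, sig_c, direction in (("HbO", hbo_sig, hbo_dir), ("HbR", hbr_sig, hbr_dir)):
            activated = (
                sig_c
                and not atypical
                and ((chrom == "HbO" and direction > 0) or (chrom == "HbR" and direction < 0))
            )
            calls.append(ActivationCall(ch, chrom, direction, activated, atypical))

    if comparison_condition is not None:
        for chrom in CHROMOPHORES:
            test_channels = (
                sig_by_chrom[chrom] if contrast_family == "significant" else list(range(1, 19))
            )
            pvals, kept = [], []
            for ch in test_channels:
                def grab(cond):
                    return responses[
                        (responses["condition"] == cond)
                        & (responses["chromophore"] == chrom)
                        & (responses["channel"] == ch)
                    ].sort_values("subject_id")["value"].to_numpy()

                x, y = grab(condition), grab(comparison_condition)
                if x.size != y.size:
                    raise ValueError("paired contrast requires matched subjects")
                res = location_test(x, y, mode="paired")
                p_perm = sign_flip_test(x - y, params)
                pvals.append(res.p_parametric)
                kept.append((ch, res, p_perm, float((x - y).mean())))
            if not pvals:
                continue
            p_adj, sig = bh_fdr(pvals, params.alpha)
            for (ch, res, p_perm, m), padj, s in zip(kept, p_adj, sig):
                rows.append(
                    {
                        "stage": "contrast",
                        "channel": ch,
                        "chromophore": chrom,
                        "t": res.statistic,
                        "df": res.df,
                        "p": res.p_parametric,
                        "p_adj": float(padj),
                        "p_permutation": p_perm,
                        "mean": m,
                        "significant": bool(s),
                    }
                )
    return calls, pd.DataFrame(rows)


def data_quality_table(
    qc: pd.DataFrame,
    groups: pd.DataFrame,
    params: StatsParams | None = None,
) -> pd.DataFrame:
    """AS-vs-QS comparison of data-quality metrics (stage-constant subjects).

    ``qc`` is tidy: subject_id, metric, value (percentage of clean data and
    valid-trial counts per condition). ``groups`` gives subject_id, group,
    stage_constant. One row per metric with the group means (SD), Welch t,
    p, pooled Cohen's d, bootstrap CI and permutation p.
    """
    params = params or StatsParams()
    keep = groups[groups["stage_constant"].fillna(False)]
    merged = qc.merge(keep[["subject_id", "group"]].drop_duplicates(), on="subject_id")
    rows = []
    for metric, sub in merged.groupby("metric", sort=False):
        a = sub[sub["group"] == "AS"]["value"].to_numpy(dtype=float)
        q = sub[sub["group"] == "QS"]["value"].to_numpy(dtype=float)
        if a.size < 2 or q.size < 2:
            raise ValueError(f"empty or singleton group for metric {metric!r}")
        res = compare_groups(a, q, params=params, variant="welch")
        rows.append(
            {
                "metric": metric,
                "AS_mean": a.mean(),
                "AS_sd": a.std(ddof=1),
                "AS_n": a.size,
                "QS_mean": q.mean(),
                "QS_sd": q.std(ddof=1),
                "QS_n": q.size,
                "t": res.statistic,
                "df": res.df,
                "p": res.p_parametric,
                "cohens_d": res.effect_size_d,
                "d_ci_low": res.d_ci[0],
                "d_ci_high": res.d_ci[1],
                "p_permutation": res.p_permutation,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run settings: simulate -> code sleep -> preprocess ->
    allocate -> analyze."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_label: str = "UK"
    seed: int = 0
    stats: StatsParams = field(default_factory=StatsParams)
    analysis_window_s: tuple[float, float] = (8.0, 16.0)
    out_dir: str | Path | None = None


def _responses_table(subject_id: str, responses: dict[str, np.ndarray]) -> list[dict]:
    rows = []
    for cond, arr in responses.items():
        for ch in range(arr.shape[0]):
            for ci, chrom in enumerate(CHROMOPHORES):
                rows.append(
                    {
                        "subject_id": subject_id,
                        "channel": ch + 1,
                        "chromophore": chrom,
                        "condition": cond,
                        "value": float(arr[ch, ci]),
                    }
                )
    return rows


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full synthetic-cohort analysis; returns a report bundle.

    The bundle holds the manifest, per-subject QC reports, the windowed
    response table, allocation and group tables, the data-quality
    comparison, ROI comparisons appropriate to the paradigm, and an
    exclusion ledger whose counts sum to the cohort size. When ``out_dir``
    is set, all tables are also written as CSV/JSON plus a run log.
    """
    scheme = default_coding_scheme()
    paradigm = (
        social_paradigm()
        if config.cohort.paradigm == "social_selectivity"
        else hand_paradigm()
    )
    subjects, manifest = generate_cohort(config.cohort, config.seed, scheme=scheme)
    ledger = {"total": len(subjects), "low_codability": 0, "low_quality": 0,
              "too_few_trials": 0, "analyzed": 0}

    qc_rows, resp_rows, qc_reports = [], [], []
    allocations: dict[str, dict[str, AllocationResult]] = {}
    trials_by_subject = {}
    for sub in subjects:
        mean_score, include = assess_codability(sub.coding_sheet, scheme)
        if not include:
            ledger["low_codability"] += 1
            logger.info("%s excluded: codability %.1f%%", sub.subject_id, mean_score)
            continue
        timeline = derive_timeline(sub.coding_sheet)
        try:
            out = pp.preprocess_subject(sub.recording, paradigm)
        except pp.SubjectExcluded as exc:
            key = "low_quality" if "channel" in str(exc) else "too_few_trials"
            ledger[key] += 1
            logger.info("%s excluded: %s", sub.subject_id, exc)
            continue
        trials = label_trials(sub.events, timeline, out["valid"])
        trials_by_subject[sub.subject_id] = trials
        if config.cohort.paradigm == "social_selectivity":
            allocations[sub.subject_id] = {"social": allocate_social(trials)}
        else:
            allocations[sub.subject_id] = {
                f"hand_{a}": allocate_hand(trials, a)
                for a in ("fam1", "habituation", "novelty")
            }
        qc_reports.append(out["qc_report"])
        qc_rows.append(
            {
                "subject_id": sub.subject_id,
                "metric": "percent_clean_data",
                "value": out["qc_report"]["percent_clean_data"],
            }
        )
        for cond, n in out["qc_report"]["n_valid_trials"].items():
            qc_rows.append(
                {"subject_id": sub.subject_id, "metric": f"valid_{cond}_trials", "value": n}
            )
        resp_rows.extend(_responses_table(sub.subject_id, out["responses"]))
        ledger["analyzed"] += 1

    responses = pd.DataFrame(resp_rows)
    qc_table = pd.DataFrame(qc_rows)
    group_table = build_analysis_groups(manifest, allocations, trials_by_subject)
    assert sum(ledger[k] for k in
               ("low_codability", "low_quality", "too_few_trials", "analyzed")) == ledger["total"]

    dq = data_quality_table(qc_table, group_table, config.stats) if not qc_table.empty else None

    roi_results = {}
    label = config.cohort_label
    if not responses.empty and not group_table.empty:
        if config.cohort.paradigm == "social_selectivity":
            roi = ROI_REGISTRY[(label, "social_activation")]
            for chrom in CHROMOPHORES:
                for cond in ("N", "V"):
                    vals = roi_mean(responses, roi, cond, chrom)
                    per_group = _split_groups(vals, group_table, "social")
                    if min(map(len, per_group.values()), default=0) >= 4:
                        roi_results[f"social_{cond}_{chrom}"] = roi_group_comparison(
                            per_group["QS"], per_group["AS"], config.stats
                        )
        else:
            roi = ROI_REGISTRY[(label, "habituation")]
            for chrom in CHROMOPHORES:
                fam1 = roi_mean(responses, roi, "Fam1", chrom)
                fam3 = roi_mean(responses, roi, "Fam3", chrom)
                contrast = (fam1 - fam3).dropna()
                per_group = _split_groups(contrast, group_table, "hand_habituation")
                if min(map(len, per_group.values()), default=0) >= 4:
                    roi_results[f"habituation_{chrom}"] = roi_group_comparison(
                        per_group["QS"], per_group["AS"], config.stats
                    )

    bundle = {
        "manifest": manifest,
        "responses": responses,
        "qc_table": qc_table,
        "qc_reports": qc_reports,
        "groups": group_table,
        "data_quality": dq,
        "roi_results": roi_results,
        "exclusion_ledger": ledger,
    }
    if config.out_dir is not None:
        _write_bundle(bundle, Path(config.out_dir), config)
    return bundle


def _split_groups(values: pd.Series, groups: pd.DataFrame, analysis: str) -> dict[str, np.ndarray]:
    g = groups[groups["analysis"] == analysis].set_index("subject_id")["group"]
    out = {}
    for stage in ("QS", "AS"):
        sids = g[g == stage].index
        out[stage] = values.reindex(sids).dropna().to_numpy()
    return out


def _write_bundle(bundle: dict, out_dir: Path, config: PipelineConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle["manifest"].to_csv(out_dir / "manifest.csv", index=False)
    bundle["responses"].to_csv(out_dir / "responses.csv", index=False)
    bundle["qc_table"].to_csv(out_dir / "qc_metrics.csv", index=False)
    bundle["groups"].to_csv(out_dir / "allocations.csv", index=False)
    if bundle["data_quality"] is not None:
        bundle["data_quality"].to_csv(out_dir / "data_quality.csv", index=False)
    with open(out_dir / "qc_reports.json", "w") as fh:
        json.dump(bundle["qc_reports"], fh, indent=1)
    roi_rows = [
        {
            "comparison": name,
            "t": r.statistic,
            "df": r.df,
            "p": r.p_parametric,
            "p_permutation": r.p_permutation,
            "cohens_d": r.effect_size_d,
            "d_ci_low": r.d_ci[0],
            "d_ci_high": r.d_ci[1],
        }
        for name, r in bundle["roi_results"].items()
    ]
    pd.DataFrame(roi_rows).to_csv(out_dir / "roi_results.csv", index=False)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(
            {
                "seed": config.seed,
                "cohort_label": config.cohort_label,
                "paradigm": config.cohort.paradigm,
                "exclusion_ledger": bundle["exclusion_ledger"],
            },
            fh,
            indent=1,
        )
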