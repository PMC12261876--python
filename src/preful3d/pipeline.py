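"""End-to-end simulated studies: simulate -> map -> stats -> report.

Reproduces the three comparison designs of a dual-center ventilation-MRI
study on synthetic cohorts:

* repeatability — first vs second measurement on each scanner, with
  Bland-Altman bias, Wilcoxon p, median between-measurement CoV, ICC(2,1),
  paired Cohen's d, and the median spatial overlap of the binary
  ventilated-volume maps;
* intercenter consistency — independent cohorts at the shared field
  strength, age-matched, bias + Wilcoxon p per parameter and measurement;
* field-strength comparison — the same subjects on the 1.5-T and 3-T
  scanner of one center, bias with percent change, Wilcoxon p, Cohen's d.

All sections derive from one simulated cohort per config; everything is
deterministic in the config seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import repstats, synth, ventmaps
from .config import StudyConfig, config_hash

__all__ = [
    "CohortData",
    "StudyReport",
    "DesignError",
    "summarize_cohort",
    "run_repeatability_study",
    "run_intercenter_study",
    "run_field_strength_study",
    "run_study",
    "plot_bland_altman",
]

logger = logging.getLogger(__name__)

PARAMETERS = tuple(repstats.PARAMETER_LABELS)


class DesignError(ValueError):
    """Raised when a study design is not realizable from the config."""


@dataclass
class CohortData:
    """Per-measurement summaries plus the binary ventilated-volume maps."""

    summaries: pd.DataFrame
    vv_maps: dict[tuple[str, str, int], dict[str, np.ndarray]]
    config: StudyConfig


@dataclass
class StudyReport:
    """Assembled report mirroring the three study tables, plus a manifest."""

    repeatability: dict[str, dict[str, pd.DataFrame]]
    intercenter: dict | None
    field_strength: dict | None
    summaries: pd.DataFrame
    manifest: dict

    def to_jsonable(self) -> dict:
        def df_records(df: pd.DataFrame):
            return df.replace({np.nan: None}).to_dict(orient="records")

        out: dict = {"manifest": self.manifest}
        out["summaries"] = df_records(self.summaries)
        out["repeatability"] = {
            scanner: {
                "table": df_records(sec["table"]),
                "overlap": df_records(sec["overlap"]),
            }
            for scanner, sec in self.repeatability.items()
        }
        if self.intercenter is not None:
            out["intercenter"] = {
                "table": df_records(self.intercenter["table"]),
                "matched_pairs": self.intercenter["matched_pairs"],
                "excluded": list(self.intercenter["excluded"]),
                "median_age_difference": self.intercenter["median_age_difference"],
            }
        else:
            out["intercenter"] = None
        if self.field_strength is not None:
            out["field_strength"] = {"table": df_records(self.field_strength["table"])}
        else:
            out["field_strength"] = None
        return out


def _as_cohort(config_or_cohort) -> CohortData:
    if isinstance(config_or_cohort, CohortData):
        return config_or_cohort
    return summarize_cohort(config_or_cohort)


def summarize_cohort(config: StudyConfig) -> CohortData:
    """Simulate every configured measurement and analyze it.

    Measurements are generated lazily and only the scalar summaries, masks,
    and binary ventilated-volume maps are retained.
    """
    config.validate()
    t0 = time.perf_counter()
    rows = []
    vv_maps: dict[tuple[str, str, int], dict[str, np.ndarray]] = {}
    kwargs = config.analysis_kwargs()
    n = 0
    for spec, meas in synth.iter_cohort_measurements(config):
        result = ventmaps.analyze_measurement(meas, **kwargs)
        key = (spec.subject_id, meas.scanner, meas.measurement_index)
        vv_maps[key] = {
            "vv_rvent": result.vv_rvent,
            "vv_fvlcm": result.vv_fvlcm,
            "mask": result.analysis_mask,
        }
        row = {
            "subject_id": spec.subject_id,
            "age": spec.age,
            "sex": spec.sex,
            "center": spec.center,
            "scanner": meas.scanner,
            "measurement": meas.measurement_index,
            **result.summary.as_dict(),
            "true_mean_rvent": float(
                meas.ground_truth.rvent_true_field[meas.analysis_mask].mean()
            ),
            "true_tidal_volume": meas.ground_truth.true_tidal_volume,
            "true_breathing_frequency": meas.ground_truth.true_breathing_frequency,
        }
        rows.append(row)
        n += 1
    logger.info("summarized %d measurements in %.2f s", n, time.perf_counter() - t0)
    return CohortData(summaries=pd.DataFrame(rows), vv_maps=vv_maps, config=config)


def _median_iqr(x: np.ndarray) -> tuple[float, float, float]:
    return (
        float(np.median(x)),
        float(np.percentile(x, 25)),
        float(np.percentile(x, 75)),
    )


def _paired_by_measurement(df: pd.DataFrame, param: str) -> repstats.PairedSample:
    """Pair measurement 1 vs 2 values of one parameter by subject."""
    piv = df.pivot_table(index="subject_id", columns="measurement", values=param)
    piv = piv.dropna()
    return repstats.PairedSample(
        ids=tuple(piv.index), x1=piv[1].to_numpy(), x2=piv[2].to_numpy()
    )


def _repeatability_row(p: repstats.PairedSample, param: str) -> dict:
    ba = repstats.bland_altman(p)
    m1 = _median_iqr(p.x1)
    m2 = _median_iqr(p.x2)
    try:
        icc = repstats.icc_absolute_agreement(p)
        icc_label = repstats.interpret_icc(icc)
    except repstats.StatsError:
        icc, icc_label = float("nan"), "undefined"
    try:
        d = repstats.cohens_d_paired(p)
        d_label = repstats.interpret_effect_size(d)
    except repstats.StatsError:
        d, d_label = float("nan"), "undefined"
    _, median_cov = repstats.pairwise_cov(p)
    return {
        "parameter": param,
        "label": repstats.PARAMETER_LABELS[param],
        "n": p.n,
        "m1_median": m1[0], "m1_q1": m1[1], "m1_q3": m1[2],
        "m2_median": m2[0], "m2_q1": m2[1], "m2_q3": m2[2],
        "bias": ba.bias, "loa_low": ba.loa_low, "loa_high": ba.loa_high,
        "p": repstats.wilcoxon_signed_rank(p),
        "median_cov": median_cov,
        "icc": icc, "icc_label": icc_label,
        "cohens_d": d, "cohens_d_label": d_label,
    }


def run_repeatability_study(config_or_cohort) -> dict[str, dict[str, pd.DataFrame]]:
    """First vs second measurement, per scanner.

    Returns, per scanner label, a parameter table (bias, p, median CoV, ICC,
    Cohen's d) and a spatial-overlap summary (median and IQR of the
    between-measurement overlap of VV_RVent and VV_FVL-CM maps). Subjects
    missing a second measurement are dropped with a log entry.
    """
    cohort = _as_cohort(config_or_cohort)
    df = cohort.summaries
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for scanner in sorted(df["scanner"].unique()):
        sub = df[df["scanner"] == scanner]
        counts = sub.groupby("subject_id")["measurement"].nunique()
        incomplete = counts[counts < 2].index.tolist()
        if incomplete:
            logger.warning(
                "scanner %s: dropping %d subject(s) without both measurements: %s",
                scanner, len(incomplete), incomplete,
            )
            sub = sub[~sub["subject_id"].isin(incomplete)]
        if sub.empty:
            continue
        rows = [
            _repeatability_row(_paired_by_measurement(sub, param), param)
            for param in PARAMETERS
        ]
        overlap_rows = []
        for map_name in ("vv_rvent", "vv_fvlcm"):
            vals = []
            for sid in sorted(sub["subject_id"].unique()):
                m1 = cohort.vv_maps[(sid, scanner, 1)]
                m2 = cohort.vv_maps[(sid, scanner, 2)]
                mask = m1["mask"] & m2["mask"]
                vals.append(
                    repstats.spatial_overlap(m1[map_name], m2[map_name], mask)
                )
            med, q1, q3 = _median_iqr(np.array(vals))
            overlap_rows.append(
                {"map": map_name, "median": med, "q1": q1, "q3": q3, "n": len(vals)}
            )
        out[scanner] = {
            "table": pd.DataFrame(rows),
            "overlap": pd.DataFrame(overlap_rows),
        }
    return out


def _common_field_strength(config: StudyConfig) -> tuple[str, str, str, str]:
    """(center_a, profile_a, center_b, profile_b) sharing a field strength."""
    if len(config.centers) < 2:
        raise DesignError("intercenter design needs two centers")
    a, b = config.centers[0], config.centers[1]
    for pa in a.profiles:
        for pb in b.profiles:
            if config.profiles[pa].field_strength == config.profiles[pb].field_strength:
                return a.name, pa, b.name, pb
    raise DesignError("no common field strength between the first two centers")


def run_intercenter_study(config_or_cohort) -> dict:
    """Age-matched comparison of two centers at the shared field strength.

    Per measurement and parameter: Bland-Altman bias (Center A − Center B)
    and two-sided Wilcoxon p over the matched pairs. Exclusions from the
    larger cohort are reported.
    """
    cohort = _as_cohort(config_or_cohort)
    config = cohort.config
    center_a, prof_a, center_b, prof_b = _common_field_strength(config)
    df = cohort.summaries

    ages_a = {
        sid: g["age"].iloc[0]
        for sid, g in df[df["center"] == center_a].groupby("subject_id")
    }
    ages_b = {
        sid: g["age"].iloc[0]
        for sid, g in df[df["center"] == center_b].groupby("subject_id")
    }
    match = repstats.age_match(ages_a, ages_b)
    logger.info(
        "age matching: %d pairs, %d excluded, median |delta age| %.1f y",
        len(match.pairs), len(match.excluded), match.median_age_difference,
    )

    rows = []
    for m in (1, 2):
        sub_a = df[(df["center"] == center_a) & (df["scanner"] == prof_a) & (df["measurement"] == m)]
        sub_b = df[(df["center"] == center_b) & (df["scanner"] == prof_b) & (df["measurement"] == m)]
        val_a = sub_a.set_index("subject_id")
        val_b = sub_b.set_index("subject_id")
        for param in PARAMETERS:
            ids, x1, x2 = [], [], []
            for id_a, id_b, _ in match.pairs:
                if id_a in val_a.index and id_b in val_b.index:
                    ids.append(f"{id_a}|{id_b}")
                    x1.append(val_a.loc[id_a, param])
                    x2.append(val_b.loc[id_b, param])
            if not ids:
                logger.warning("intercenter: no pairs for %s m%d; row skipped", param, m)
                continue
            p = repstats.PairedSample(tuple(ids), np.array(x1), np.array(x2))
            ba = repstats.bland_altman(p)
            rows.append(
                {
                    "parameter": param,
                    "label": repstats.PARAMETER_LABELS[param],
                    "measurement": m,
                    "n": p.n,
                    "bias": ba.bias,
                    "loa_low": ba.loa_low,
                    "loa_high": ba.loa_high,
                    "p": repstats.wilcoxon_signed_rank(p),
                }
            )
    return {
        "table": pd.DataFrame(rows),
        "centers": (center_a, center_b),
        "profiles": (prof_a, prof_b),
        "matched_pairs": [list(p) for p in match.pairs],
        "excluded": match.excluded,
        "median_age_difference": match.median_age_difference,
    }


def _field_strength_pair(config: StudyConfig) -> tuple[str, str, str]:
    for c in config.centers:
        strengths = {p: config.profiles[p].field_strength for p in c.profiles}
        if len(set(strengths.values())) >= 2:
            ordered = sorted(c.profiles, key=lambda p: strengths[p])
            return c.name, ordered[0], ordered[-1]
    raise DesignError("no center scans subjects at two field strengths")


def run_field_strength_study(config_or_cohort) -> dict:
    """Same-subject comparison of the two field strengths at one center.

    The lower field strength is the reference; bias = reference − comparison
    (positive bias: reference reads higher), percent change is relative to
    the reference cohort mean, effect size is paired Cohen's d.
    """
    cohort = _as_cohort(config_or_cohort)
    config = cohort.config
    center, prof_ref, prof_cmp = _field_strength_pair(config)
    df = cohort.summaries[cohort.summaries["center"] == center]

    rows = []
    for m in (1, 2):
        ref = df[(df["scanner"] == prof_ref) & (df["measurement"] == m)].set_index("subject_id")
        cmp_ = df[(df["scanner"] == prof_cmp) & (df["measurement"] == m)].set_index("subject_id")
        common = sorted(set(ref.index) & set(cmp_.index))
        for param in PARAMETERS:
            p = repstats.PairedSample(
                tuple(common),
                ref.loc[common, param].to_numpy(),
                cmp_.loc[common, param].to_numpy(),
            )
            ba = repstats.bland_altman(p)
            try:
                d = repstats.cohens_d_paired(p)
                d_label = repstats.interpret_effect_size(d)
            except repstats.StatsError:
                d, d_label = float("nan"), "undefined"
            ref_mean = float(p.x1.mean())
            pct = (
                repstats.percent_change(ba.bias, ref_mean)
                if ref_mean != 0
                else float("nan")
            )
            rows.append(
                {
                    "parameter": param,
                    "label": repstats.PARAMETER_LABELS[param],
                    "measurement": m,
                    "n": p.n,
                    "bias": ba.bias,
                    "percent_change": pct,
                    "p": repstats.wilcoxon_signed_rank(p),
                    "cohens_d": d,
                    "cohens_d_label": d_label,
                }
            )
    return {
        "table": pd.DataFrame(rows),
        "center": center,
        "reference_profile": prof_ref,
        "comparison_profile": prof_cmp,
    }


def run_study(config: StudyConfig) -> StudyReport:
    """Simulate the cohort once and build every realizable report section."""
    import preful3d

    t0 = time.perf_counter()
    cohort = summarize_cohort(config)
    repeat = run_repeatability_study(cohort)
    try:
        intercenter = run_intercenter_study(cohort)
    except DesignError as exc:
        logger.info("intercenter section skipped: %s", exc)
        intercenter = None
    try:
        fieldstrength = run_field_strength_study(cohort)
    except DesignError as exc:
        logger.info("field-strength section skipped: %s", exc)
        fieldstrength = None
    logger.info("study completed in %.2f s", time.perf_counter() - t0)
    # no timestamps or runtimes in the manifest: report JSON is byte-identical
    # for identical (config, seed)
    manifest = {
        "seed": config.seed,
        "package_version": preful3d.__version__,
        "config_hash": config_hash(config),
        "n_measurements": int(len(cohort.summaries)),
    }
    return StudyReport(
        repeatability=repeat,
        intercenter=intercenter,
        field_strength=fieldstrength,
        summaries=cohort.summaries,
        manifest=manifest,
    )


def plot_bland_altman(p: repstats.PairedSample, ax=None, title: str | None = None):
    """Bland-Altman scatter: per-subject mean vs difference with bias/LoA lines."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ba = repstats.bland_altman(p)
    means = (p.x1 + p.x2) / 2.0
    ax.scatter(means, p.differences, s=18, alpha=0.8)
    for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of measurements")
    ax.set_ylabel("difference (1 - 2)")
    if title:
        ax.set_title(title)
    return ax
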