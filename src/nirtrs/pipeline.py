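"""End-to-end analysis: from a study bundle to the group-level tables.

Reproduces the analysis sequence of the two-condition block design:

1. baseline-ratio normalisation and 13-period segmentation of each
   subject's two-channel oxy/deoxy change rates;
2. two-way repeated-measures ANOVA (condition x period, Greenhouse-
   Geisser corrected) per chromophore and channel;
3. per-period paired t tests (simple minus creative, so a creative
   increase prints a negative t) with Cohen's d and post-hoc power;
4. VAS comparisons gated on Shapiro-Wilk normality (paired t if both
   conditions normal, Wilcoxon signed-rank otherwise);
5. per-period heart-rate and LF/HF correlations against the oxy change
   rate with robust outlier exclusion and the normality-gated
   Pearson/Spearman choice;
6. pooled (both conditions) Pearson correlations between the immediate
   post-task oxy change and each VAS item.

Everything is deterministic given the input bundle and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import autonomic, stats
from .autonomic import p_from_correlation
from .design import CONDITIONS, ExperimentDesign
from .io import RunConfig
from .simulate import CHANNELS, VAS_ITEMS, SyntheticExperiment

__all__ = [
    "ReportBundle",
    "period_matrices",
    "invert_tpsf_stream",
    "run_full_pipeline",
    "write_report",
]


def invert_tpsf_stream(stream, window=None, init=None):
    """Recover a hemoglobin concentration series from a photon-level TPSF
    stream: each 3-wavelength sample is fitted for its absorption triplet
    and unmixed by least squares. Returns (oxy_um, deoxy_um) arrays."""
    from .chromophore import unmix
    from .inversion import fit_tpsf

    oxy, deoxy = [], []
    for tpsfs in stream:
        mua = np.empty(len(tpsfs))
        wl = np.empty(len(tpsfs))
        for j, tpsf in enumerate(tpsfs):
            res = fit_tpsf(tpsf, window=window, init=init)
            mua[j] = res.props.mua
            wl[j] = tpsf.wavelength
        state = unmix(mua, wl)
        oxy.append(state.oxy)
        deoxy.append(state.deoxy)
    return np.asarray(oxy), np.asarray(deoxy)


@dataclass
class ReportBundle:
    table_vas: pd.DataFrame
    table_anova: pd.DataFrame
    table_oxy: pd.DataFrame
    table_deoxy: pd.DataFrame
    corr_hr: pd.DataFrame
    corr_lfhf: pd.DataFrame
    corr_vas: pd.DataFrame
    log: dict = field(default_factory=dict)


def period_matrices(
    experiment: SyntheticExperiment, design: ExperimentDesign | None = None
) -> dict[str, np.ndarray]:
    """Per-subject 13-period mean change rates.

    Returns ``{"oxy": arr, "deoxy": arr}`` with arrays of shape
    (subject, condition, channel, period), conditions ordered as
    ``CONDITIONS`` (simple, creative).
    """
    design = design or experiment.design
    subjects = sorted({k[0] for k in experiment.hb})
    out = {
        chrom: np.full((len(subjects), len(CONDITIONS), len(CHANNELS), design.n_periods), np.nan)
        for chrom in ("oxy", "deoxy")
    }
    for si, subj in enumerate(subjects):
        for ci, cond in enumerate(CONDITIONS):
            channels = experiment.hb[(subj, cond)]
            for hi, chan in enumerate(CHANNELS):
                s = channels[chan]
                for chrom, vals in (("oxy", s.oxy_um), ("deoxy", s.deoxy_um)):
                    rate = stats.normalize_baseline(vals, design)
                    out[chrom][si, ci, hi] = stats.segment_periods(rate, design)
    return out


def _paired_table(
    matrix: np.ndarray, design: ExperimentDesign, alpha: float
) -> pd.DataFrame:
    """Per-period simple-vs-creative paired comparisons for both channels."""
    isimple = CONDITIONS.index("simple")
    icreative = CONDITIONS.index("creative")
    rows = []
    for hi, chan in enumerate(CHANNELS):
        for p, label in enumerate(design.periods):
            creative = matrix[:, icreative, hi, p]
            simple = matrix[:, isimple, hi, p]
            res = stats.paired_t(simple, creative, alpha=alpha)
            rows.append(
                {
                    "channel": chan,
                    "period": label,
                    "mean_creative": creative.mean(),
                    "sd_creative": creative.std(ddof=1),
                    "mean_simple": simple.mean(),
                    "sd_simple": simple.std(ddof=1),
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "d": abs(res.d),
                    "power": res.power,
                }
            )
    return pd.DataFrame(rows)


def _anova_table(matrices: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for chrom in ("oxy", "deoxy"):
        for hi, chan in enumerate(CHANNELS):
            res = stats.rm_anova(matrices[chrom][:, :, hi, :])
            rows.append(
                {
                    "chromophore": chrom,
                    "channel": chan,
                    "F_condition": res.condition.F,
                    "p_condition": res.condition.p,
                    "F_period": res.period.F,
                    "p_period": res.period.p_corr,
                    "F_interaction": res.interaction.F,
                    "p_interaction": res.interaction.p_corr,
                    "epsilon_gg_period": res.epsilon_gg_period,
                    "epsilon_gg_interaction": res.epsilon_gg_interaction,
                    "mauchly_p_period": res.mauchly_p_period,
                }
            )
    return pd.DataFrame(rows)


def _vas_table(vas: pd.DataFrame, alpha: float) -> pd.DataFrame:
    rows = []
    for item in VAS_ITEMS:
        sub = vas[vas["item"] == item].pivot(
            index="subject", columns="condition", values="score"
        )
        simple = sub["simple"].to_numpy()
        creative = sub["creative"].to_numpy()
        norm_s = stats.shapiro_wilk(simple)
        norm_c = stats.shapiro_wilk(creative)
        both_normal = (
            not norm_s.degenerate
            and not norm_c.degenerate
            and norm_s.p > alpha
            and norm_c.p > alpha
        )
        row = {
            "item": item,
            "mean_simple": simple.mean(),
            "sd_simple": simple.std(ddof=1),
            "mean_creative": creative.mean(),
            "sd_creative": creative.std(ddof=1),
        }
        if both_normal:
            res = stats.paired_t(simple, creative, alpha=alpha)
            row.update(test="paired_t", statistic=abs(res.t), df=res.df, p=res.p)
        else:
            res = stats.wilcoxon_signed_rank(creative, simple)
            row.update(test="wilcoxon", statistic=abs(res.w), df=np.nan, p=res.p)
        rows.append(row)
    return pd.DataFrame(rows)


def _autonomic_tables(
    experiment: SyntheticExperiment,
    oxy_matrix: np.ndarray,
    design: ExperimentDesign,
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-period correlations of the creative-condition oxy change rate
    with heart rate and LF/HF; outliers excluded per period per channel."""
    subjects = sorted({k[0] for k in experiment.hb})
    icreative = CONDITIONS.index("creative")
    n = len(subjects)
    hr = np.full((n, design.n_periods), np.nan)
    lfhf = np.full((n, design.n_periods), np.nan)
    for si, subj in enumerate(subjects):
        series = experiment.rr.get((subj, "creative"))
        if series is None:
            continue
        hr[si] = autonomic.mean_hr_per_period(series, design)
        for p, (lo, hi) in enumerate(design.period_windows()):
            try:
                lfhf[si, p] = autonomic.lf_hf(
                    series,
                    window=(lo, hi),
                    resample_hz=config.hrv_resample_hz,
                    segment_s=config.hrv_segment_s,
                ).lf_hf
            except ValueError:
                pass
    excluded = 0

    def corr_rows(auto: np.ndarray) -> list[dict]:
        nonlocal excluded
        rows = []
        for hi, chan in enumerate(CHANNELS):
            for p, label in enumerate(design.periods):
                x = oxy_matrix[:, icreative, hi, p]
                y = auto[:, p]
                keep = np.isfinite(x) & np.isfinite(y)
                for v in (x, y):
                    if keep.sum() >= 5:
                        keep &= autonomic.detect_outliers(
                            np.where(keep, v, np.nan), k=config.outlier_k
                        )
                excluded += int((np.isfinite(x) & np.isfinite(y)).sum() - keep.sum())
                if keep.sum() < 3:
                    continue
                res = autonomic.correlate_gated(
                    x[keep], y[keep], alpha=config.normality_alpha
                )
                rows.append(
                    {
                        "channel": chan,
                        "period": label,
                        "method": res.method,
                        "n": res.n,
                        "coefficient": res.coefficient,
                        "p": res.p,
                    }
                )
        return rows

    corr_hr = pd.DataFrame(corr_rows(hr))
    corr_lfhf = pd.DataFrame(corr_rows(lfhf))
    return corr_hr, corr_lfhf, {"autonomic_points_excluded": excluded}


def _vas_correlations(
    experiment: SyntheticExperiment, oxy_matrix: np.ndarray, design: ExperimentDesign
) -> pd.DataFrame:
    """Pooled (both conditions, 2n points) Pearson correlations between the
    immediate post-task oxy change rate and each VAS item."""
    subjects = sorted({k[0] for k in experiment.hb})
    ipost1 = list(design.periods).index("posttask_rest1")
    vas = experiment.vas.pivot_table(
        index=["subject", "condition"], columns="item", values="score"
    )
    rows = []
    for hi, chan in enumerate(CHANNELS):
        oxy, scores = [], {item: [] for item in VAS_ITEMS}
        for si, subj in enumerate(subjects):
            for ci, cond in enumerate(CONDITIONS):
                oxy.append(oxy_matrix[si, ci, hi, ipost1])
                for item in VAS_ITEMS:
                    scores[item].append(vas.loc[(subj, cond), item])
        oxy = np.asarray(oxy)
        for item in VAS_ITEMS:
            y = np.asarray(scores[item])
            r = float(np.corrcoef(y, oxy)[0, 1])
            rows.append(
                {
                    "channel": chan,
                    "item": item,
                    "method": "pearson",
                    "n": oxy.shape[0],
                    "coefficient": r,
                    "p": p_from_correlation(r, oxy.shape[0]),
                }
            )
    return pd.DataFrame(rows)


def run_full_pipeline(
    experiment: SyntheticExperiment, config: RunConfig | None = None
) -> ReportBundle:
    """Run the complete analysis chain on a study bundle."""
    config = config or RunConfig()
    design = config.design()
    matrices = period_matrices(experiment, design)
    alpha = config.normality_alpha
    table_oxy = _paired_table(matrices["oxy"], design, alpha)
    table_deoxy = _paired_table(matrices["deoxy"], design, alpha)
    table_anova = _anova_table(matrices)
    table_vas = _vas_table(experiment.vas, alpha)
    corr_hr, corr_lfhf, auto_log = _autonomic_tables(
        experiment, matrices["oxy"], design, config
    )
    corr_vas = _vas_correlations(experiment, matrices["oxy"], design)
    log = {
        "n_subjects": len({k[0] for k in experiment.hb}),
        "config_hash": config.hash(),
        "manifest": experiment.manifest,
        **auto_log,
    }
    return ReportBundle(
        table_vas=table_vas,
        table_anova=table_anova,
        table_oxy=table_oxy,
        table_deoxy=table_deoxy,
        corr_hr=corr_hr,
        corr_lfhf=corr_lfhf,
        corr_vas=corr_vas,
        log=log,
    )


def write_report(bundle: ReportBundle, outdir: str | Path) -> None:
    """Write the report bundle as CSV tables plus a JSON run log."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.table_vas.to_csv(outdir / "table1_vas.csv", index=False)
    bundle.table_anova.to_csv(outdir / "table2_anova.csv", index=False)
    bundle.table_oxy.to_csv(outdir / "table3_oxy.csv", index=False)
    bundle.table_deoxy.to_csv(outdir / "table4_deoxy.csv", index=False)
    bundle.corr_hr.to_csv(outdir / "corr_heart_rate.csv", index=False)
    bundle.corr_lfhf.to_csv(outdir / "corr_lfhf.csv", index=False)
    bundle.corr_vas.to_csv(outdir / "corr_vas.csv", index=False)
    (outdir / "run_log.json").write_text(
        json.dumps(bundle.log, indent=2, sort_keys=True, default=str) + "\n"
    )
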