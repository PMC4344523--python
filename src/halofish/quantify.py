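"""Per-nucleus and per-group statistics of Halo-FISH experiments.

Everything downstream of detection is assembled here: per-nucleus counts and
kb contents by strand and compartment, the extrachromosomal fraction of
total telomere-repeat DNA, telomere:centromere core ratios, G/C strand
biases, colocalization fractions, length-distribution summaries,
centromere-based cell-cycle binning, and the group-level comparisons
(Welch t-tests, OLS content-vs-centromere regression, G2/G1 fold changes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .calibration import CalibrationModel, intensity_to_bp
from .foci import FocusRecord, pair_colocalized
from .segmentation import CompartmentMap


@dataclass
class LengthStats:
    mean_kb: float = float("nan")
    median_kb: float = float("nan")
    pct_below_50: float = float("nan")
    pct_above_200: float = float("nan")
    mean_median_ratio: float = float("nan")


def length_distribution_stats(lengths_kb) -> LengthStats:
    """Mean/median and the <50 / >200 kb bin fractions of a length sample."""
    arr = np.asarray(lengths_kb, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return LengthStats()
    mean = float(arr.mean())
    median = float(np.median(arr))
    return LengthStats(
        mean_kb=mean,
        median_kb=median,
        pct_below_50=float(100.0 * np.mean(arr < 50.0)),
        pct_above_200=float(100.0 * np.mean(arr > 200.0)),
        mean_median_ratio=mean / median if median > 0 else float("nan"),
    )


def _bias_pct(a: float, b: float) -> float:
    """Symmetric percent difference: 100 * (a - b) / mean(a, b)."""
    m = 0.5 * (a + b)
    if m == 0:
        return float("nan")
    return 100.0 * (a - b) / m


@dataclass
class NucleusMetrics:
    """All per-nucleus quantities reported by the pipeline."""

    nucleus_id: str
    halo_count_G: int = 0
    halo_count_C: int = 0
    core_count_G: int = 0
    core_count_C: int = 0
    centromere_count_core: int = 0
    centromere_count_halo: int = 0
    halo_content_kb_G: float = 0.0
    halo_content_kb_C: float = 0.0
    core_content_kb_G: float = 0.0
    core_content_kb_C: float = 0.0
    ectr_fraction_G: float = float("nan")  # % of strand content that is ECTR
    ectr_fraction_C: float = float("nan")
    tel_cen_ratio_G: float = float("nan")
    tel_cen_ratio_C: float = float("nan")
    coloc_fraction_halo: float = float("nan")
    coloc_fraction_core: float = float("nan")
    number_bias: float = float("nan")  # % more G than C, symmetric denominator
    content_bias: float = float("nan")
    cell_cycle_bin: str | None = None
    length_stats_G: LengthStats = field(default_factory=LengthStats)
    length_stats_C: LengthStats = field(default_factory=LengthStats)
    core_volume_um3: float = float("nan")

    def as_row(self) -> dict:
        d = asdict(self)
        for strand in ("G", "C"):
            ls = d.pop(f"length_stats_{strand}")
            for k, v in ls.items():
                d[f"halo_len_{k}_{strand}"] = v
        return d


def _strand_foci(foci_by_channel: dict, strand: str) -> list[FocusRecord]:
    channel = "TelG" if strand == "G" else "TelC"
    return list(foci_by_channel.get(channel, []))


def _content_kb(foci: list[FocusRecord]) -> float:
    vals = [f.estimated_bp for f in foci if math.isfinite(f.estimated_bp)]
    return float(sum(vals)) / 1000.0


def summarize_nucleus(
    compartments: CompartmentMap | None,
    foci_by_channel: dict[str, list[FocusRecord]],
    calibration: CalibrationModel | None = None,
    nucleus_id: str = "",
    coloc_max_distance_um: float = 0.3,
    modal_2n_count: int | None = None,
) -> NucleusMetrics:
    """Compute all per-nucleus metrics from thresholded, length-estimated foci.

    Foci must already carry ``passes_threshold``; when a calibration is given,
    ``estimated_bp`` is (re)computed here for telomere-channel foci that are
    not border-clipped.  Missing channels yield the corresponding null fields.
    """
    m = NucleusMetrics(nucleus_id=nucleus_id)
    if compartments is not None:
        m.core_volume_um3 = compartments.core_volume_um3

    if calibration is not None:
        for channel in ("TelG", "TelC"):
            if channel not in calibration.channels:
                continue
            for f in foci_by_channel.get(channel, []):
                f.estimated_bp = (
                    float("nan")
                    if f.border_clipped
                    else intensity_to_bp(f.integrated_intensity, calibration,
                                         channel)
                )

    passing: dict[str, dict[str, list[FocusRecord]]] = {}
    for strand in ("G", "C"):
        sf = [f for f in _strand_foci(foci_by_channel, strand)
              if f.passes_threshold]
        passing[strand] = {
            "halo": [f for f in sf if f.compartment == "halo"],
            "core": [f for f in sf if f.compartment == "core"],
        }

    m.halo_count_G = len(passing["G"]["halo"])
    m.halo_count_C = len(passing["C"]["halo"])
    m.core_count_G = len(passing["G"]["core"])
    m.core_count_C = len(passing["C"]["core"])
    m.halo_content_kb_G = _content_kb(passing["G"]["halo"])
    m.halo_content_kb_C = _content_kb(passing["C"]["halo"])
    m.core_content_kb_G = _content_kb(passing["G"]["core"])
    m.core_content_kb_C = _content_kb(passing["C"]["core"])

    for strand in ("G", "C"):
        halo = getattr(m, f"halo_content_kb_{strand}")
        core = getattr(m, f"core_content_kb_{strand}")
        total = halo + core
        if total > 0:
            setattr(m, f"ectr_fraction_{strand}", 100.0 * halo / total)

    cen = foci_by_channel.get("CEN")
    if cen is not None:
        cen_pass = [f for f in cen if f.passes_threshold]
        m.centromere_count_core = sum(
            1 for f in cen_pass if f.compartment == "core"
        )
        m.centromere_count_halo = sum(
            1 for f in cen_pass if f.compartment == "halo"
        )
        if m.centromere_count_core > 0:
            m.tel_cen_ratio_G = m.core_count_G / m.centromere_count_core
            m.tel_cen_ratio_C = m.core_count_C / m.centromere_count_core
        if modal_2n_count is not None and m.centromere_count_core > 0:
            m.cell_cycle_bin = assign_cell_cycle_bin(
                m.centromere_count_core, modal_2n_count
            )

    m.number_bias = _bias_pct(m.halo_count_G, m.halo_count_C)
    m.content_bias = _bias_pct(m.halo_content_kb_G, m.halo_content_kb_C)

    for comp in ("halo", "core"):
        g, c = passing["G"][comp], passing["C"][comp]
        if g or c:
            _, fraction = pair_colocalized(g, c, coloc_max_distance_um)
            setattr(m, f"coloc_fraction_{comp}", fraction)

    m.length_stats_G = length_distribution_stats(
        [f.estimated_bp / 1000.0 for f in passing["G"]["halo"]
         if math.isfinite(f.estimated_bp)]
    )
    m.length_stats_C = length_distribution_stats(
        [f.estimated_bp / 1000.0 for f in passing["C"]["halo"]
         if math.isfinite(f.estimated_bp)]
    )
    return m


def assign_cell_cycle_bin(
    centromere_count: int,
    modal_2n_count: int,
    g1_max_factor: float = 1.25,
    g2_min_factor: float = 1.75,
) -> str:
    """Bin a nucleus into G1/S/G2 from its core centromere focus count.

    Replication doubles centromere counts, so counts near the modal 2N value
    are G1, counts near twice it are G2, and intermediates are S.
    """
    if centromere_count <= 0:
        raise ValueError("centromere_count must be positive")
    if modal_2n_count <= 0:
        raise ValueError("modal_2n_count must be positive")
    if centromere_count <= g1_max_factor * modal_2n_count:
        return "G1"
    if centromere_count >= g2_min_factor * modal_2n_count:
        return "G2"
    return "S"


@dataclass
class TTestResult:
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    iqr_a: tuple[float, float]
    iqr_b: tuple[float, float]


def compare_groups(values_a, values_b) -> TTestResult:
    """Welch two-sample t-test with median/IQR descriptive statistics."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        raise ValueError("zero variance in both groups; t-test degenerate")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    qa = np.percentile(a, [25, 75])
    qb = np.percentile(b, [25, 75])
    return TTestResult(
        t_statistic=float(t),
        p_value=float(p),
        n_a=int(a.size),
        n_b=int(b.size),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        iqr_a=(float(qa[0]), float(qa[1])),
        iqr_b=(float(qb[0]), float(qb[1])),
    )


def compare_metric(metrics_a, metrics_b, metric_name: str) -> TTestResult:
    """Welch t-test on one named NucleusMetrics field between two groups."""
    get = lambda ms: [getattr(m, metric_name) for m in ms]
    return compare_groups(get(metrics_a), get(metrics_b))


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    r_squared: float
    n: int


def regress_content_vs_centromeres(metrics_list) -> RegressionResult:
    """OLS of total (G+C) Halo ECTR content on core centromere count.

    Replication doubles centromeres as cells traverse S phase, so a positive
    slope links ECTR production to cell-cycle progression.
    """
    if len(metrics_list) < 3:
        raise ValueError("need n >= 3 nuclei")
    x = np.array([m.centromere_count_core for m in metrics_list], dtype=float)
    y = np.array(
        [m.halo_content_kb_G + m.halo_content_kb_C for m in metrics_list],
        dtype=float,
    )
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: centromere counts do not vary")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_ci95=(float(ci[1][0]), float(ci[1][1])),
        r_squared=float(fit.rsquared),
        n=len(metrics_list),
    )


def cell_cycle_fold_changes(metrics_list) -> dict:
    """Per-bin means and G2/G1 fold changes of ECTR count and median length.

    Returns per-bin mean total Halo counts and mean per-nucleus median
    lengths (pooled strands), plus their G2/G1 ratios (NaN with a warning
    value of None when a bin is empty).
    """
    bins: dict[str, list] = {"G1": [], "S": [], "G2": []}
    for m in metrics_list:
        if m.cell_cycle_bin in bins:
            bins[m.cell_cycle_bin].append(m)
    out: dict = {"per_bin": {}}
    for name, ms in bins.items():
        if not ms:
            out["per_bin"][name] = {"n": 0, "mean_count": float("nan"),
                                    "mean_median_len_kb": float("nan")}
            continue
        counts = [m.halo_count_G + m.halo_count_C for m in ms]
        med_lens = []
        for m in ms:
            vals = [v for v in (m.length_stats_G.median_kb,
                                m.length_stats_C.median_kb)
                    if math.isfinite(v)]
            if vals:
                med_lens.append(float(np.mean(vals)))
        out["per_bin"][name] = {
            "n": len(ms),
            "mean_count": float(np.mean(counts)),
            "mean_median_len_kb": (
                float(np.mean(med_lens)) if med_lens else float("nan")
            ),
        }
    g1, g2 = out["per_bin"]["G1"], out["per_bin"]["G2"]
    if g1["n"] and g2["n"] and g1["mean_count"] > 0:
        out["count_fold_g2_g1"] = g2["mean_count"] / g1["mean_count"]
    else:
        out["count_fold_g2_g1"] = float("nan")
    if (
        g1["n"] and g2["n"]
        and math.isfinite(g1["mean_median_len_kb"])
        and math.isfinite(g2["mean_median_len_kb"])
        and g1["mean_median_len_kb"] > 0
    ):
        out["length_fold_g2_g1"] = (
            g2["mean_median_len_kb"] / g1["mean_median_len_kb"]
        )
    else:
        out["length_fold_g2_g1"] = float("nan")
    return out


def group_summary(metrics_df: pd.DataFrame, by: str = "group") -> pd.DataFrame:
    """Median and interquartile range of every numeric metric per group."""
    num = metrics_df.select_dtypes(include=[np.number])
    grouped = metrics_df.groupby(by)
    rows = []
    for name, idx in grouped.groups.items():
        sub = num.loc[idx]
        row = {"group": name, "n_nuclei": len(idx)}
        for col in num.columns:
            vals = sub[col].dropna()
            if vals.empty:
                continue
            row[f"{col}_median"] = float(vals.median())
            row[f"{col}_iqr_low"] = float(vals.quantile(0.25))
            row[f"{col}_iqr_high"] = float(vals.quantile(0.75))
        rows.append(row)
    return pd.DataFrame(rows)


def metrics_to_dataframe(metrics_list) -> pd.DataFrame:
    return pd.DataFrame([m.as_row() for m in metrics_list])
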