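"""Relative quantification (2^-ddCt) and differential expression for qPCR panels.

The workflow mirrors the standard TaqMan card analysis for circulating
miRNAs: raw cycle-threshold (Ct) values are normalized to the mean of
endogenous reference miRNAs (dCt), converted to relative quantities
RQ = 2^-ddCt against a calibrator, and compared between case and control
groups with the Mann-Whitney test. Because Ct is already a log2 abundance
scale (one PCR cycle ~ one doubling), the "geometric mean of the reference
miRNAs" prescribed for normalization is the arithmetic mean of their Ct
values, and the group log2 fold change is (minus) the difference of group
mean dCt.

A statsmodels-style front end is provided: build a :class:`QpcrExperiment`
from a long-format Ct table and call :meth:`~QpcrExperiment.fit` to obtain a
:class:`QpcrResults` object with the per-miRNA estimates, p-values and a
``summary()`` table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "UNDETECTED",
    "CT_CUTOFF",
    "read_ct_table",
    "write_ct_table",
    "normalize_reference",
    "relative_quantity",
    "mann_whitney",
    "differential_expression",
    "fold_change_display",
    "reporter_assay",
    "QpcrExperiment",
    "QpcrResults",
    "ReporterResult",
    "MissingReferenceError",
]

#: Sentinel emitted by qPCR instruments for reactions that never crossed the
#: fluorescence threshold.
UNDETECTED = "Undetermined"

#: Default detection cutoff: a Ct at or above 40 cycles is treated as undetected.
CT_CUTOFF = 40.0

_UNDETECTED_TOKENS = {"undetermined", "undetected", "na", "nan", ""}


class MissingReferenceError(ValueError):
    """A sample has no detected replicate for one of the reference miRNAs."""


def read_ct_table(path) -> pd.DataFrame:
    """Read a long-format Ct table (columns sample, group, mirna, replicate, ct).

    ``NA`` / ``Undetermined`` (case-insensitive) in the ``ct`` column are parsed
    as missing (undetected).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample": str, "group": str, "mirna": str})
    required = {"sample", "group", "mirna", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table is missing required columns: {sorted(missing)}")
    ct = df["ct"]
    if ct.dtype == object:
        mask = ct.astype(str).str.strip().str.lower().isin(_UNDETECTED_TOKENS)
        df["ct"] = pd.to_numeric(ct.where(~mask), errors="raise")
    df["replicate"] = df["replicate"].astype(int)
    return df


def write_ct_table(df: pd.DataFrame, path) -> None:
    """Write a Ct table, emitting the :data:`UNDETECTED` sentinel for missing Ct."""
    out = df.copy()
    out["ct"] = out["ct"].map(lambda v: UNDETECTED if pd.isna(v) else repr(float(v)))
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    out.to_csv(path, sep=sep, index=False)


def _detected(df: pd.DataFrame, ct_cutoff: float) -> pd.Series:
    return df["ct"].notna() & (df["ct"] < ct_cutoff)


def normalize_reference(
    ct: pd.DataFrame,
    reference_ids: list[str],
    ct_cutoff: float = CT_CUTOFF,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Collapse replicates and normalize target Ct to the reference-miRNA mean.

    Per (sample, miRNA) the detected replicates (Ct < ``ct_cutoff``) are averaged
    in Ct space. The per-sample reference summary is the arithmetic mean of the
    averaged reference Cts — the geometric mean of the corresponding linear
    abundances. A target measurement with fewer than ``min_replicates`` detected
    replicates is dropped (emitted as missing); a reference needs at least one.

    Returns a tidy frame (sample, group, mirna, delta_ct) with reference miRNAs
    excluded from the targets.

    Raises
    ------
    MissingReferenceError
        If any sample lacks every replicate of some reference miRNA.
    ValueError
        If a reference id is absent from the table.
    """
    reference_ids = list(reference_ids)
    present = set(ct["mirna"].unique())
    unknown = [r for r in reference_ids if r not in present]
    if unknown:
        raise ValueError(f"Reference miRNA(s) not present in the Ct table: {unknown}")
    if not reference_ids:
        raise ValueError("At least one reference miRNA is required")

    df = ct.copy()
    df["detected"] = _detected(df, ct_cutoff)
    grouped = (
        df[df["detected"]]
        .groupby(["sample", "group", "mirna"], sort=False)["ct"]
        .agg(mean_ct="mean", n_detected="size")
        .reset_index()
    )

    refs = grouped[grouped["mirna"].isin(reference_ids)]
    ref_counts = refs.groupby("sample")["mirna"].nunique()
    all_samples = df["sample"].unique()
    bad = [
        s
        for s in all_samples
        if ref_counts.get(s, 0) < len(reference_ids)
    ]
    if bad:
        raise MissingReferenceError(
            f"Sample(s) with no detected replicate for a reference miRNA: {sorted(bad)}"
        )
    ref_summary = refs.groupby("sample")["mean_ct"].mean().rename("ref_ct")

    targets = grouped[
        ~grouped["mirna"].isin(reference_ids)
        & (grouped["n_detected"] >= min_replicates)
    ].copy()
    targets = targets.join(ref_summary, on="sample")
    targets["delta_ct"] = targets["mean_ct"] - targets["ref_ct"]
    return targets[["sample", "group", "mirna", "delta_ct"]].reset_index(drop=True)


def relative_quantity(
    dct: pd.DataFrame,
    calibrator: str | float | dict = "control",
) -> pd.DataFrame:
    """Per-sample relative quantity RQ = 2^-(dCt - calibrator dCt).

    ``calibrator`` is either a group label (the per-miRNA calibrator dCt is the
    mean dCt of that group, so the calibrator group's geometric-mean RQ is 1),
    an explicit dCt value applied to every miRNA, or a mapping miRNA -> dCt.

    miRNAs for which the calibrator cannot be resolved (empty calibrator group)
    are flagged ``quantifiable=False`` with RQ missing.
    """
    out = dct.copy()
    if isinstance(calibrator, str):
        cal = (
            out[out["group"] == calibrator]
            .groupby("mirna")["delta_ct"]
            .mean()
        )
        out["cal_dct"] = out["mirna"].map(cal)
    elif isinstance(calibrator, dict):
        out["cal_dct"] = out["mirna"].map(calibrator)
    else:
        out["cal_dct"] = float(calibrator)
    out["quantifiable"] = out["cal_dct"].notna()
    out["rq"] = 2.0 ** -(out["delta_ct"] - out["cal_dct"])
    return out[["sample", "group", "mirna", "delta_ct", "rq", "quantifiable"]]


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (U, p).

    U counts pairs with x_i > y_j plus half the ties. The null distribution is
    exact when the combined sample size is at most 20 and there are no ties,
    and otherwise a normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def differential_expression(
    dct: pd.DataFrame,
    case: str = "case",
    control: str = "control",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-miRNA differential expression between two groups.

    log2FC = -(mean dCt_case - mean dCt_control); FC = 2^log2FC (the ratio of
    the group geometric-mean RQs). p-values come from the Mann-Whitney test on
    per-sample RQ (equivalently dCt — the transform is monotone) and are
    BH-adjusted across the miRNAs tested in both groups. The volcano table
    pairs log2FC with -log10 p and flags significance at raw p < ``alpha``.

    miRNAs detected in only one group are excluded from testing (and from the
    BH family) and carry ``tested=False``.
    """
    rq = relative_quantity(dct, calibrator=control)
    rows = []
    for mirna, sub in rq.groupby("mirna", sort=True):
        xs = sub.loc[sub["group"] == case, "rq"].to_numpy()
        ys = sub.loc[sub["group"] == control, "rq"].to_numpy()
        dx = sub.loc[sub["group"] == case, "delta_ct"].to_numpy()
        dy = sub.loc[sub["group"] == control, "delta_ct"].to_numpy()
        tested = xs.size > 0 and ys.size > 0
        if tested:
            log2fc = -(dx.mean() - dy.mean())
            _, p = mann_whitney(xs, ys)
            mean_rq_case = float(2.0 ** np.mean(np.log2(xs)))
            mean_rq_control = float(2.0 ** np.mean(np.log2(ys)))
        else:
            log2fc, p = np.nan, np.nan
            mean_rq_case = mean_rq_control = np.nan
        rows.append(
            {
                "mirna": mirna,
                "log2fc": log2fc,
                "fc": 2.0 ** log2fc if tested else np.nan,
                "p_raw": p,
                "n_case_detected": int(xs.size),
                "n_control_detected": int(ys.size),
                "mean_rq_case": mean_rq_case,
                "mean_rq_control": mean_rq_control,
                "tested": tested,
            }
        )
    de = pd.DataFrame(rows)
    de["p_adj"] = np.nan
    tested_mask = de["tested"].to_numpy()
    if tested_mask.any():
        de.loc[tested_mask, "p_adj"] = multipletests(
            de.loc[tested_mask, "p_raw"], method="fdr_bh"
        )[1]
    de["significant"] = de["p_raw"] < alpha
    volcano = de.loc[
        de["tested"], ["mirna", "log2fc", "p_raw", "significant"]
    ].copy()
    volcano["neg_log10_p"] = -np.log10(volcano["p_raw"])
    volcano = volcano[["mirna", "log2fc", "neg_log10_p", "significant"]]
    cols = [
        "mirna", "log2fc", "fc", "p_raw", "p_adj",
        "n_case_detected", "n_control_detected",
        "mean_rq_case", "mean_rq_control", "tested", "significant",
    ]
    return de[cols].reset_index(drop=True), volcano.reset_index(drop=True)


def fold_change_display(log2fc: float, sig_figs: int = 3) -> float:
    """Linear fold change 2^log2FC rounded to ``sig_figs`` significant figures."""
    fc = 2.0 ** float(log2fc)
    if fc == 0 or not math.isfinite(fc):
        return fc
    ndigits = sig_figs - 1 - int(math.floor(math.log10(abs(fc))))
    return round(fc, ndigits)


# --------------------------------------------------------------------------
# Dual-luciferase reporter statistics
# --------------------------------------------------------------------------

@dataclass
class ReporterResult:
    """Summary of a dual-luciferase knockdown comparison.

    ``normalized`` holds, per construct, the mean and SD (over independent
    experiments) of the Renilla/Firefly ratio scaled so the empty-vector
    control-miRNA wells average 1 on each plate.
    """

    normalized: pd.DataFrame
    reduction_pct: float
    p_value: float
    n_experiments: int


def reporter_assay(
    plate: pd.DataFrame,
    control_construct: str = "empty+ctrl",
    test_pair: tuple[str, str] = ("utr+ctrl", "utr+mir"),
) -> ReporterResult:
    """Normalize a dual-luciferase plate set and test for target knockdown.

    Each well's ratio is renilla/firefly; within each experiment (plate) every
    ratio is divided by the mean ratio of the ``control_construct`` wells, so
    the control averages 1 by construction. Per construct, experiment-level
    means are averaged over the independent experiments. The percent reduction
    compares the miRNA-co-transfected 3'UTR construct against its control-miRNA
    counterpart, with a two-tailed two-sample t-test on the experiment-level
    normalized ratios. Wells with non-positive firefly signal (the divisor)
    are rejected with a warning; with fewer than two experiments no p-value is
    computed.
    """
    df = plate.copy()
    bad = df["firefly"] <= 0
    if bad.any():
        warnings.warn(
            f"Rejected {int(bad.sum())} well(s) with non-positive firefly signal",
            stacklevel=2,
        )
        df = df[~bad]
    if control_construct not in set(df["construct"]):
        raise ValueError(f"No wells for control construct {control_construct!r}")
    df["ratio"] = df["renilla"] / df["firefly"]
    ctrl_means = (
        df[df["construct"] == control_construct]
        .groupby("experiment_index")["ratio"]
        .mean()
    )
    df["norm_ratio"] = df["ratio"] / df["experiment_index"].map(ctrl_means)
    per_exp = (
        df.groupby(["construct", "experiment_index"])["norm_ratio"]
        .mean()
        .reset_index()
    )
    summary = (
        per_exp.groupby("construct")["norm_ratio"]
        .agg(mean="mean", sd="std", n_experiments="size")
        .reset_index()
    )
    ctrl_name, mir_name = test_pair
    a = per_exp.loc[per_exp["construct"] == ctrl_name, "norm_ratio"].to_numpy()
    b = per_exp.loc[per_exp["construct"] == mir_name, "norm_ratio"].to_numpy()
    if a.size == 0 or b.size == 0:
        raise ValueError(f"Missing wells for test constructs {test_pair}")
    reduction = float((1.0 - b.mean() / a.mean()) * 100.0)
    n_exp = int(min(a.size, b.size))
    if n_exp >= 2:
        p = float(stats.ttest_ind(a, b).pvalue)
    else:
        p = float("nan")
    return ReporterResult(
        normalized=summary, reduction_pct=reduction, p_value=p, n_experiments=n_exp
    )


# --------------------------------------------------------------------------
# Model / Results front end
# --------------------------------------------------------------------------

class QpcrExperiment:
    """Two-group qPCR relative-quantification experiment.

    Parameters
    ----------
    ct : DataFrame
        Long-format Ct table (sample, group, mirna, replicate, ct).
    references : list of str
        Endogenous reference miRNAs used for dCt normalization.
    case, control : str
        Group labels; ``control`` doubles as the calibrator group.
    ct_cutoff : float
        Detection cutoff in cycles.
    alpha : float
        Raw-p significance threshold for the headline flag.
    """

    def __init__(
        self,
        ct: pd.DataFrame,
        references: list[str],
        case: str = "case",
        control: str = "control",
        ct_cutoff: float = CT_CUTOFF,
        min_replicates: int = 2,
        alpha: float = 0.05,
    ):
        self.ct = ct
        self.references = list(references)
        self.case = case
        self.control = control
        self.ct_cutoff = ct_cutoff
        self.min_replicates = min_replicates
        self.alpha = alpha

    @classmethod
    def from_csv(cls, path, references, **kwargs) -> "QpcrExperiment":
        return cls(read_ct_table(path), references, **kwargs)

    def fit(self) -> "QpcrResults":
        dct = normalize_reference(
            self.ct, self.references, self.ct_cutoff, self.min_replicates
        )
        rq = relative_quantity(dct, calibrator=self.control)
        de, volcano = differential_expression(
            dct, case=self.case, control=self.control, alpha=self.alpha
        )
        return QpcrResults(self, dct, rq, de, volcano)


@dataclass
class QpcrResults:
    """Fitted results of a :class:`QpcrExperiment`."""

    model: QpcrExperiment
    delta_ct: pd.DataFrame
    rq: pd.DataFrame
    de: pd.DataFrame
    volcano: pd.DataFrame
    _roc: pd.DataFrame | None = field(default=None, repr=False)

    def roc(self) -> pd.DataFrame:
        """Per-miRNA ROC/AUC discrimination of case vs control on RQ scores."""
        from .roc import roc_auc

        rows = []
        for mirna, sub in self.rq.groupby("mirna", sort=True):
            labels = (sub["group"] == self.model.case).to_numpy()
            if labels.all() or not labels.any():
                continue
            r = roc_auc(sub["rq"].to_numpy(), labels, mirna_id=mirna)
            rows.append(
                {"mirna": mirna, "auc": r.auc, "se_auc": r.se_auc, "p_value": r.p_value}
            )
        self._roc = pd.DataFrame(rows)
        return self._roc

    def summary(self) -> str:
        """Human-readable per-miRNA table in the style of a fitted-model report."""
        de = self.de.copy()
        de["fc_display"] = de["log2fc"].map(
            lambda v: fold_change_display(v) if np.isfinite(v) else np.nan
        )
        lines = [
            "qPCR relative quantification (2^-ddCt)",
            f"  case group: {self.model.case}   control/calibrator: {self.model.control}",
            f"  references: {', '.join(self.model.references)}   "
            f"Ct cutoff: {self.model.ct_cutoff:g}",
            "",
            f"{'miRNA':<16}{'log2FC':>10}{'FC':>8}{'p':>12}{'p(BH)':>12}{'sig':>5}",
        ]
        for _, r in de.iterrows():
            sig = "*" if r["significant"] else ""
            lines.append(
                f"{r['mirna']:<16}{r['log2fc']:>10.4f}{r['fc_display']:>8.3g}"
                f"{r['p_raw']:>12.3g}{r['p_adj']:>12.3g}{sig:>5}"
            )
        return "\n".join(lines)
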