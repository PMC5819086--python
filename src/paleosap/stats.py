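"""Recovery statistics and significance tests for cross-species searches.

Covers four questions about an error-tolerant cross-species search relative
to the ground-truth search: how identification decays with evolutionary
distance, how peptide length drives non-identification (logistic model),
whether error-tolerant recovery exceeds the non-error-tolerant subset
(paired t-test over datasets), and whether unidentified proteins are
faster-evolving than identified ones (Welch t-test on dN/dS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .classify import Outcome, OutcomeRecord
from .filters import accept_proteins


def _outcome_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = [
        (r.evolutionary_distance, int(r.outcome), r.peptide_length)
        for r in records
    ]
    return pd.DataFrame(rows, columns=["evolutionary_distance", "outcome", "peptide_length"])


def recovery_by_distance(records) -> pd.Series:
    """Fraction of mutable PSMs identified (outcomes 1-3), per SAP count.

    The index covers every distance from 1 up to at least 3, reporting 0
    where no mutable PSM at that distance was identified (and NaN where no
    mutable PSM at that distance exists at all would be meaningless, so such
    distances report 0 over 0 as 0 only when inside the padded range).
    """
    df = _outcome_frame(records)
    if df.empty:
        return pd.Series(dtype=float, name="identified_fraction")
    if (df["evolutionary_distance"] < 1).any():
        raise ValueError("recovery_by_distance expects mutable PSMs (distance >= 1)")
    identified = df["outcome"] != int(Outcome.UNMATCHED)
    grouped = identified.groupby(df["evolutionary_distance"]).mean()
    top = max(3, int(df["evolutionary_distance"].max()))
    out = grouped.reindex(range(1, top + 1), fill_value=0.0)
    out.name = "identified_fraction"
    return out


@dataclass
class LogisticFit:
    """Logistic regression of P(unidentified) on peptide length.

    The response is *non*-identification (outcome 4), so a positive slope
    means longer mutable peptides are more often lost. ``separation`` flags
    a degenerate fit (only one response class, or perfect separation), in
    which case the estimates are unusable but no exception is raised.
    """

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    n: int
    separation: bool = False
    _cov: Optional[np.ndarray] = None

    def predict(self, lengths: Sequence[float]) -> pd.DataFrame:
        """P(unidentified) with a 1-SD band, per length."""
        x = np.asarray(lengths, dtype=float)
        eta = self.intercept + self.slope * x
        if self._cov is not None:
            X = np.column_stack([np.ones_like(x), x])
            se_eta = np.sqrt(np.einsum("ij,jk,ik->i", X, self._cov, X))
        else:
            se_eta = np.full_like(x, np.nan)
        inv = lambda e: 1.0 / (1.0 + np.exp(-e))
        return pd.DataFrame(
            {
                "length": x,
                "p_unidentified": inv(eta),
                "lower_1sd": inv(eta - se_eta),
                "upper_1sd": inv(eta + se_eta),
            }
        )


def fit_length_logistic(records) -> LogisticFit:
    """Fit unidentified(0/1) ~ peptide length by maximum likelihood."""
    df = _outcome_frame(records)
    if df.empty:
        raise ValueError("no records to fit")
    y = (df["outcome"] == int(Outcome.UNMATCHED)).astype(float).to_numpy()
    x = df["peptide_length"].astype(float).to_numpy()
    n = len(y)
    if y.min() == y.max():
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, n, separation=True)
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=False, maxiter=200)
        except Exception:
            return LogisticFit(np.nan, np.nan, np.nan, np.nan, n, separation=True)
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    separated = bool(not res.mle_retvals.get("converged", True) or np.any(bse > 1e3))
    return LogisticFit(
        intercept=float(params[0]),
        slope=float(params[1]),
        se_intercept=float(bse[0]),
        se_slope=float(bse[1]),
        n=n,
        separation=separated,
        _cov=np.asarray(res.cov_params(), dtype=float),
    )


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    pvalue: float


def paired_search_comparison(
    values_a: Sequence[float], values_b: Sequence[float]
) -> TTestResult:
    """Classical paired t-test (two-sided) on per-dataset values.

    Raises on fewer than two pairs or on zero variance of the differences
    (including identical vectors and constant shifts), where the statistic
    is undefined.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.isclose(d.std(ddof=1), 0.0):
        raise ValueError("zero variance of paired differences")
    res = sps.ttest_rel(a, b)
    return TTestResult(float(res.statistic), float(n - 1), float(res.pvalue))


def compare_dnds(records: pd.DataFrame) -> TTestResult:
    """Welch t-test of dN/dS between identified and unidentified proteins.

    ``records`` needs columns ``dnds`` (>= 0) and ``group`` with values
    "identified" / "unidentified". The statistic is reported as
    identified minus unidentified, with Welch-Satterthwaite degrees of
    freedom.
    """
    for col in ("dnds", "group"):
        if col not in records.columns:
            raise ValueError(f"missing column {col!r}")
    if (records["dnds"] < 0).any():
        raise ValueError("dnds values must be >= 0")
    ident = records.loc[records["group"] == "identified", "dnds"].to_numpy(float)
    unident = records.loc[records["group"] == "unidentified", "dnds"].to_numpy(float)
    if len(ident) < 2 or len(unident) < 2:
        raise ValueError("each group needs at least two proteins")
    res = sps.ttest_ind(ident, unident, equal_var=False)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def position_recovery(
    truth_positions: Iterable[Tuple[str, int]],
    observed_mutable_psms: pd.DataFrame,
) -> float:
    """Fraction of informative positions covered by >= 1 observed mutable PSM.

    A position counts as recovered when any observed mutable PSM spans it,
    regardless of how many do and of whether the suggested substitution was
    correct.
    """
    truth = list(truth_positions)
    if not truth:
        raise ValueError("empty truth position set")
    df = observed_mutable_psms
    if df.empty:
        return 0.0
    covered = 0
    for acc, pos in truth:
        sub = df[df["accession"] == acc]
        if ((sub["start"] <= pos) & (sub["end"] >= pos)).any():
            covered += 1
    return covered / len(truth)


def recovery_stats(
    search1: pd.DataFrame,
    cross: pd.DataFrame,
    scan_distance: Mapping[Tuple[str, str], int],
) -> pd.DataFrame:
    """Per-dataset recovery of proteins, PSMs and mutable PSMs.

    ``scan_distance`` maps (dataset_id, scan_id) to the peptide's
    evolutionary distance in this database (ground truth, from search 1).
    The non-error-tolerant search is emulated as the subset of the
    cross-species PSMs with no suggested substitutions — a standard search
    can only ever match the unmutated database sequence. All counts are also
    returned normalized to the ground-truth search of the same dataset.
    """
    rows = []
    non_et = cross[cross["substitutions"] == ""]
    for ds, s1 in search1.groupby("dataset_id"):
        cr = cross[cross["dataset_id"] == ds]
        ne = non_et[non_et["dataset_id"] == ds]
        dist = s1.apply(
            lambda r: scan_distance.get((r["dataset_id"], r["scan_id"]), 0), axis=1
        )
        mutable_keys = set(
            zip(s1.loc[dist >= 1, "dataset_id"], s1.loc[dist >= 1, "scan_id"])
        )
        observed = set(zip(cr["dataset_id"], cr["scan_id"])) & mutable_keys
        rows.append(
            {
                "dataset_id": ds,
                "n_proteins_s1": len(accept_proteins(s1)),
                "n_psms_s1": len(s1),
                "n_mutable_expected": len(mutable_keys),
                "n_proteins_et": len(accept_proteins(cr)),
                "n_psms_et": len(cr),
                "n_proteins_non_et": len(accept_proteins(ne)),
                "n_psms_non_et": len(ne),
                "n_mutable_observed": len(observed),
            }
        )
    out = pd.DataFrame(rows).set_index("dataset_id")
    for kind in ("et", "non_et"):
        out[f"proteins_{kind}_norm"] = out[f"n_proteins_{kind}"] / out["n_proteins_s1"]
        out[f"psms_{kind}_norm"] = out[f"n_psms_{kind}"] / out["n_psms_s1"]
    out["mutable_recovered_frac"] = np.where(
        out["n_mutable_expected"] > 0,
        out["n_mutable_observed"] / out["n_mutable_expected"],
        np.nan,
    )
    return out
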