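"""Evaluation statistics for carbohydrate-estimation studies.

Implements the evaluation machinery of a with/without-system comparison:
per-meal signed/absolute/percentage errors, summary statistics with the
+/-20 g clinical band (an absolute error of 20 g or more significantly
affects postprandial glycemia, which makes the band the design target),
under/over-estimation balance, numerator/denominator success rates,
outlier-participant exclusion, size-stratified summaries, and an
independent two-sample Mann-Whitney U test (exact by enumeration for
small samples, normal approximation with tie correction otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import SchemaError

SIZE_LABELS = ("small", "medium", "large")
REQUIRED_COLUMNS = ("meal_id", "size", "true_g", "self_g", "system_g")


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (matches printed percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).copy_abs().quantize(q, rounding=ROUND_HALF_UP)
                 * (1 if x >= 0 else -1))


@dataclass
class SuccessCounts:
    """numerator successes out of denominator attempts."""

    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise SchemaError("denominator must be positive")
        if not (0 <= self.numerator <= self.denominator):
            raise SchemaError("numerator must be in [0, denominator]")


@dataclass
class ErrorSummary:
    """Summary of per-meal estimation errors (grams and percent)."""

    n: int
    mae_g: float
    sd_g: float
    mape_pct: float
    sd_pct: float
    frac_within_band: float
    frac_under: float
    frac_over: float
    band_g: float = 20.0

    @property
    def pct_within_band(self) -> float:
        return round_half_away(100.0 * self.frac_within_band)


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"estimate table missing columns: {sorted(missing)}")
    bad = table[~(table["true_g"] > 0)]
    if not bad.empty:
        raise SchemaError(
            f"true_g must be positive; offending meal_id(s): "
            f"{bad['meal_id'].tolist()[:5]}")
    key = ["meal_id"] + (["participant_id"] if "participant_id" in table.columns else [])
    if table.duplicated(subset=key).any():
        raise SchemaError("duplicate meal_id x participant_id rows")
    return table


def compute_errors(table: pd.DataFrame, which: str) -> pd.DataFrame:
    """Per-meal signed, absolute and percentage errors for one estimator.

    ``which`` selects the ``self`` (participant) or ``system`` estimate;
    signed error is estimate minus truth, percentage is |error|/truth x 100.
    """
    if which not in ("self", "system"):
        raise ValueError("which must be 'self' or 'system'")
    if len(table) == 0:
        raise SchemaError("empty estimate table")
    validate_table(table)
    est = table[f"{which}_g"].to_numpy(dtype=float)
    true = table["true_g"].to_numpy(dtype=float)
    signed = est - true
    out = table.copy()
    out["signed_g"] = signed
    out["abs_g"] = np.abs(signed)
    out["pct"] = np.abs(signed) / true * 100.0
    return out


def summarize(errors: pd.DataFrame, band_g: float = 20.0) -> ErrorSummary:
    """Mean/SD of absolute and percentage errors plus band and balance rates.

    "Within band" is a strict inequality (|error| < band_g); "under" and
    "over" are signed error < 0 and > 0 (exact zeros count as neither).
    """
    if len(errors) == 0:
        raise SchemaError("no error rows to summarize")
    a = errors["abs_g"].to_numpy(dtype=float)
    p = errors["pct"].to_numpy(dtype=float)
    s = errors["signed_g"].to_numpy(dtype=float)
    n = len(a)
    sd = float(np.std(a, ddof=1)) if n > 1 else 0.0
    sd_p = float(np.std(p, ddof=1)) if n > 1 else 0.0
    return ErrorSummary(
        n=n,
        mae_g=float(np.mean(a)),
        sd_g=sd,
        mape_pct=float(np.mean(p)),
        sd_pct=sd_p,
        frac_within_band=float(np.mean(a < band_g)),
        frac_under=float(np.mean(s < 0)),
        frac_over=float(np.mean(s > 0)),
        band_g=band_g,
    )


def success_rate(counts: SuccessCounts) -> float:
    """Percentage to one decimal (ties away from zero): 86/114 -> 75.4."""
    return round_half_away(100.0 * counts.numerator / counts.denominator)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    ra = ranks[: len(a)].sum()
    return float(ra - len(a) * (len(a) + 1) / 2.0)


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sample Mann-Whitney U (U of group A) with a two-sided p value.

    Exact p by enumeration of all C(nA+nB, nA) rank assignments when
    nA + nB <= 12 and there are no ties; otherwise a normal approximation
    with midrank tie correction and continuity correction.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = len(a), len(b)
    u = _u_statistic(a, b)
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)

    if na + nb <= 12 and not has_ties:
        # enumerate U over all labelings of the sorted combined sample
        n = na + nb
        counts: dict[float, int] = {}
        for pos in combinations(range(n), na):
            ra = sum(pos) + na  # ranks are positions+1
            ui = ra - na * (na + 1) / 2.0
            counts[ui] = counts.get(ui, 0) + 1
        total = comb(n, na)
        p_le = sum(c for ui, c in counts.items() if ui <= u) / total
        p_ge = sum(c for ui, c in counts.items() if ui >= u) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u, float(p)

    n = na + nb
    mu = na * nb / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (n * (n - 1))
    sigma2 = na * nb / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(abs(z))
    return u, float(min(p, 1.0))


def exclude_outlier_participants(table: pd.DataFrame, *,
                                 percentile: float = 95.0,
                                 min_fraction_beyond: float = 0.5
                                 ) -> tuple[pd.DataFrame, list]:
    """Drop participants whose self-estimates are consistently extreme.

    A meal is "extreme" when its absolute self-estimation error exceeds
    the given percentile of all meals' absolute errors; a participant is
    excluded when more than ``min_fraction_beyond`` of their meals are
    extreme (the pattern of a consistent extreme over/under-estimator).
    Returns the filtered copy and the removed participant ids.
    """
    if "participant_id" not in table.columns:
        raise SchemaError("participant_id column required for outlier exclusion")
    err = compute_errors(table, "self")
    cutoff = np.percentile(err["abs_g"].to_numpy(), percentile)
    extreme = err["abs_g"] > cutoff
    removed = []
    for pid, grp in err.groupby("participant_id"):
        if extreme[grp.index].mean() > min_fraction_beyond:
            removed.append(pid)
    out = table[~table["participant_id"].isin(removed)].copy()
    if len(out) == 0:
        raise SchemaError("outlier rule removed every participant")
    return out, removed


def size_stratified_summary(table: pd.DataFrame, which: str,
                            band_g: float = 20.0) -> dict[str, ErrorSummary]:
    """One ErrorSummary per meal-size category present in the table."""
    unknown = set(table["size"]) - set(SIZE_LABELS)
    if unknown:
        raise SchemaError(f"unknown size labels: {sorted(unknown)}")
    out = {}
    for size in SIZE_LABELS:
        sub = table[table["size"] == size]
        if len(sub) == 0:
            continue
        out[size] = summarize(compute_errors(sub, which), band_g)
    return out


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_estimate_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_table(df)


def format_report(table: pd.DataFrame, band_g: float = 20.0) -> str:
    """Plain-text with/without-system comparison in printed-table layout."""
    lines = [f"n = {len(table)} meals, clinical band = +/-{band_g:g} g", ""]
    header = (f"{'':18s}{'Abs error g, mean (SD)':>24s}"
              f"{'Abs % error, mean (SD)':>24s}{'|err| < band, n (%)':>22s}")
    lines.append(header)
    summaries = {}
    for which, label in (("self", "Without system"), ("system", "With system")):
        s = summarize(compute_errors(table, which), band_g)
        summaries[which] = s
        n_in = int(round(s.frac_within_band * s.n))
        lines.append(
            f"{label:18s}"
            f"{s.mae_g:>15.2f} ({s.sd_g:.2f})"
            f"{s.mape_pct:>16.1f} ({s.sd_pct:.1f})"
            f"{n_in:>12d}/{s.n} ({s.pct_within_band:.1f})")
    u, p = mann_whitney_u(
        compute_errors(table, "self")["abs_g"],
        compute_errors(table, "system")["abs_g"])
    lines.append("")
    lines.append(f"Mann-Whitney U = {u:g}, two-sided p = {p:.4g}")
    return "\n".join(lines)
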