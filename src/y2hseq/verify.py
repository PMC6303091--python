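"""Consistency checks recomputed from the shipped reference tables.

The printed candidate tables are internally redundant: the SNR column must
equal the ratio of the two FPKM columns, the imputation-flagged rows must
all encode the same imputed count against one sequencing total (so
FPKM_EMPTY x length is constant across them and implies that total), and
the tier split must coincide with the bait-FPKM cutoff.  These checks are
what `y2hseq fixtures-verify` runs; they are also the package's regression
net for the fixture transcription itself.

All printed values carry 3–4 decimals, so a recomputed ratio can differ
from the printed one by the propagated rounding of its inputs; the checks
use an exact interval bound (each printed number is its true value
+/- half an ULP of the printed precision).
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .io import load_paper_fixture
from .quantify import fpkm_value

__all__ = [
    "snr_consistency",
    "implied_empty_total",
    "threshold_retention",
    "verify_fixtures",
]

#: half an ULP of a value printed at 3 decimals
_HALF_ULP = 0.0005


def snr_consistency(df: pd.DataFrame) -> Tuple[float, int]:
    """Check SNR = FPKM_bait / FPKM_empty for every row of a candidate fixture.

    Returns ``(max relative error, number of rows outside the rounding
    interval)``.  A row is outside only if the printed SNR cannot be
    explained by any true FPKM pair within half an ULP of the printed
    FPKMs.
    """
    fe = df["fpkm_empty"].to_numpy(float)
    fb = df["fpkm_bait"].to_numpy(float)
    snr = df["snr"].to_numpy(float)
    ratio = fb / fe
    rel_err = np.abs(ratio - snr) / snr
    lo = (fb - _HALF_ULP) / (fe + _HALF_ULP) - _HALF_ULP
    hi = (fb + _HALF_ULP) / (fe - _HALF_ULP) + _HALF_ULP
    outside = int(np.sum((snr < lo) | (snr > hi)))
    return float(rel_err.max()), outside


def implied_empty_total(df: pd.DataFrame, impute_value: int = 1) -> Tuple[float, float]:
    """Coefficient of variation of FPKM_EMPTY x length over flagged rows,
    and the EMPTY-screen sequencing total those rows imply.

    A flagged row has imputed empty count ``impute_value``, so
    FPKM_EMPTY = 1e9 * impute_value / (L * T): the product FPKM x L is the
    constant 1e9 * impute_value / T, from which T is recovered.
    """
    flagged = df[df["flagged"]]
    if flagged.empty:
        raise ValueError("fixture has no flagged rows")
    product = (flagged["fpkm_empty"] * flagged["length_bp"]).to_numpy(float)
    cv = float(product.std(ddof=0) / product.mean())
    total = 1e9 * impute_value / product.mean()
    return cv, float(total)


def threshold_retention(df: pd.DataFrame, threshold: float) -> Dict[str, int]:
    """Retention bookkeeping of a candidate fixture under ``snr > threshold``.

    ``declared_total`` is the table's own maximum printed rank (the printed
    numbering has gaps, so it exceeds the row count)."""
    retained = df[df["snr"] > threshold]
    return {
        "rows": int(len(df)),
        "retained_rows": int(len(retained)),
        "declared_total": int(df["rank"].max()),
        "known": int(df["known"].sum()),
        "high_tier": int((df["tier"] == "HIGH").sum()),
        "known_high_tier": int((df["known"] & (df["tier"] == "HIGH")).sum()),
    }


def verify_fixtures() -> Dict[str, Tuple[bool, str]]:
    """Run every fixture-based check; returns name -> (pass, message)."""
    t3 = load_paper_fixture("T3")
    t4 = load_paper_fixture("T4")
    results: Dict[str, Tuple[bool, str]] = {}

    for name, df in (("T3", t3), ("T4", t4)):
        max_err, outside = snr_consistency(df)
        results[f"snr_recomputation_{name}"] = (
            outside == 0,
            f"max relative error {max_err:.4%}, {outside} rows outside rounding interval",
        )

    for name, df in (("T3", t3), ("T4", t4)):
        cv, total = implied_empty_total(df)
        results[f"imputation_consistency_{name}"] = (
            cv < 0.005,
            f"CV {cv:.4%} over {int(df['flagged'].sum())} flagged rows; "
            f"implied EMPTY total {total:,.0f} fragments",
        )

    r3 = threshold_retention(t3, 7.2)
    results["ninja_retention"] = (
        r3["retained_rows"] == r3["rows"]
        and r3["known"] == 7
        and r3["known_high_tier"] == 7
        and r3["high_tier"] == 7,
        f"{r3['retained_rows']}/{r3['rows']} rows pass SNR>7.2; "
        f"{r3['known']} known, all in the high tier; declared total {r3['declared_total']}",
    )
    r4 = threshold_retention(t4, 6.0)
    results["tpl_retention"] = (
        r4["retained_rows"] == r4["rows"] and r4["known"] == 12,
        f"{r4['retained_rows']}/{r4['rows']} rows pass SNR>6.0; "
        f"{r4['known']} known; declared total {r4['declared_total']}",
    )

    atcka2 = t4[t4["gene_id"] == "AT3G50000"]
    ok = (
        len(atcka2) == 1
        and atcka2["tier"].iloc[0] == "HIGH"
        and atcka2["ear"].iloc[0] == ""
        and float(atcka2["snr"].iloc[0]) > 6.0
    )
    results["atcka2_retained_without_motif"] = (
        ok,
        "AT3G50000 (ATCKA2) retained in the high tier with no EAR annotation "
        "(candidate calling never filters on motifs)",
    )
    return results
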