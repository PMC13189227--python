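"""Count-based RIP-seq quantification: RPKM/TPM and J2-IP enrichment ratios.

Consumes stranded per-region read counts produced upstream (alignment and
strand-sorting are out of scope here) and computes:

* RPKM (reads per kilobase per million mapped) and its TPM renormalization
  (per-library values sum to 1e6);
* the mean per-site ratio of J2-IP to cytoplasmic-total coverage over
  inverted-repeat Alu insertion sites (dsRNA enrichment);
* the ratio of summed intron TPM to summed 3'UTR TPM, stratified by Alu
  category (relative cytoplasmic dsRNA expression of introns vs 3'UTRs).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alu_catalog import AluCategory

logger = logging.getLogger(__name__)

__all__ = [
    "rpkm_table",
    "rpkm_to_tpm",
    "ir_alu_enrichment",
    "intron_vs_utr_expression",
]

REGION_TYPES = ("intron", "three_prime_utr", "five_prime_utr", "exon")


def rpkm_table(regions: pd.DataFrame, total: float | None = None) -> pd.DataFrame:
    """Add ``rpkm`` and ``tpm`` columns to a per-region count table.

    ``regions`` needs columns ``region_id``, ``region_type``, ``category``,
    ``length`` and ``count``.  ``total`` defaults to the library's summed
    counts; rpkm = count / (length/1e3) / (total/1e6).
    """
    required = {"region_id", "region_type", "category", "length", "count"}
    missing = required - set(regions.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (regions["length"] < 1).any():
        raise ValueError("all lengths must be >= 1")
    if total is None:
        total = float(regions["count"].sum())
    if total <= 0:
        raise ValueError("total mapped reads must be > 0")
    out = regions.copy()
    out["rpkm"] = out["count"] / (out["length"] / 1e3) / (total / 1e6)
    out["tpm"] = rpkm_to_tpm(out["rpkm"].to_numpy())
    return out


def rpkm_to_tpm(rpkms: Sequence[float]) -> np.ndarray:
    """tpm_i = rpkm_i / sum(rpkm) * 1e6; scale-invariant, sums to 1e6."""
    arr = np.asarray(rpkms, dtype=float)
    s = arr.sum()
    if s <= 0:
        raise ValueError("all RPKM values are zero")
    return arr / s * 1e6


def ir_alu_enrichment(
    ip_coverage: Mapping[str, float],
    total_coverage: Mapping[str, float],
    direction: str = "ip_over_total",
) -> tuple[float, int]:
    """Mean per-site coverage ratio at IR Alu sites.

    Returns ``(mean ratio, n_excluded)`` where sites with zero denominator
    coverage are excluded from the mean and tallied.  ``direction`` selects
    IP/total (default) or total/IP.
    """
    if direction not in ("ip_over_total", "total_over_ip"):
        raise ValueError(f"unknown direction {direction!r}")
    sites = sorted(set(ip_coverage) & set(total_coverage))
    if not sites:
        raise ValueError("no paired coverage sites")
    ratios = []
    excluded = 0
    for s in sites:
        num, den = ip_coverage[s], total_coverage[s]
        if direction == "total_over_ip":
            num, den = den, num
        if den == 0:
            excluded += 1
            continue
        ratios.append(num / den)
    if not ratios:
        raise ValueError("no usable sites (all zero-denominator)")
    return float(np.mean(ratios)), excluded


def intron_vs_utr_expression(
    table: pd.DataFrame,
    numerator_type: str = "intron",
    denominator_type: str = "three_prime_utr",
) -> dict[AluCategory, float]:
    """Per-Alu-category ratio of summed intron TPM to summed 3'UTR TPM.

    Strata missing either region type are omitted with a warning.
    """
    if "tpm" not in table.columns:
        raise ValueError("table must carry a 'tpm' column (see rpkm_table)")
    out: dict[AluCategory, float] = {}
    for cat in AluCategory:
        stratum = table[table["category"] == cat.value]
        num = stratum.loc[stratum["region_type"] == numerator_type, "tpm"].sum()
        den_rows = stratum[stratum["region_type"] == denominator_type]
        if stratum.empty or den_rows.empty or stratum[stratum["region_type"] == numerator_type].empty:
            logger.warning("category %s lacks %s or %s regions; omitted", cat.value, numerator_type, denominator_type)
            continue
        den = den_rows["tpm"].sum()
        if den == 0:
            logger.warning("category %s has zero %s TPM; omitted", cat.value, denominator_type)
            continue
        out[cat] = float(num / den)
    return out
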