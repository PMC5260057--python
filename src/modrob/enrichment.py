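"""Two-group annotation-term enrichment via a two-proportion z-test.

Given two disjoint gene groups (typically the largest module versus all
remaining modules) and a local gene→term annotation table, each term's
prevalence in the two groups is compared with the pooled two-proportion
z statistic

    z = (p1 − p2) / sqrt( p̂(1−p̂)(1/n1 + 1/n2) ),   p̂ = (k1+k2)/(n1+n2)

with a two-sided p-value from the standard normal.  Percentages are
reported against the number of genes in each group that carry at least one
annotation (the mapped-gene denominator); raw group sizes are carried
alongside.  P-values are reported unadjusted; an optional
Benjamini-Hochberg column can be added.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CATEGORIES = ("cellular component", "molecular function", "biological process")

ANNOTATION_COLUMNS = ("gene", "term_id", "term_name", "category")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a ``gene<TAB>term_id<TAB>term_name<TAB>category`` TSV."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=ANNOTATION_COLUMNS, comment="#", dtype=str
    )
    return validate_annotations(df)


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns {sorted(missing)}")
    if df.empty:
        raise ValueError("annotation table is empty")
    df = df.copy()
    df["category"] = df["category"].str.strip().str.lower()
    bad = sorted(set(df["category"]) - set(CATEGORIES))
    if bad:
        raise ValueError(f"unknown annotation categories {bad}; expected {CATEGORIES}")
    before = len(df)
    df = df.drop_duplicates(subset=["gene", "term_id"])
    if len(df) < before:
        logger.warning("dropped %d duplicate (gene, term) records", before - len(df))
    return df.reset_index(drop=True)


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z statistic and two-sided normal p-value.

    A pooled proportion of exactly 0 or 1 has zero variance; that degenerate
    case returns (0.0, 1.0) with a warning — both groups then agree exactly.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        logger.warning("degenerate pooled proportion %g; returning z=0, p=1", pooled)
        return 0.0, 1.0
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return z, min(p, 1.0)


def differential_enrichment(
    group1: Iterable[str],
    group2: Iterable[str],
    annotations: pd.DataFrame,
    include_bh: bool = False,
) -> pd.DataFrame:
    """Rank terms by how differently they are enriched in two gene groups.

    Counts, per term, the annotated genes in each group; tests each term
    with the pooled z-test using mapped-gene denominators; sorts ascending
    by p then by \\|z\\| descending (term id breaks remaining ties).  Terms
    annotating no gene in either group are omitted.
    """
    g1 = set(group1)
    g2 = set(group2)
    if not g1 or not g2:
        raise ValueError("both groups must be nonempty")
    overlap = g1 & g2
    if overlap:
        raise ValueError(f"groups are not disjoint: {sorted(overlap)[:5]} ...")
    ann = validate_annotations(annotations)
    mapped1 = len(g1 & set(ann["gene"]))
    mapped2 = len(g2 & set(ann["gene"]))
    if mapped1 == 0 or mapped2 == 0:
        raise ValueError("a group has no annotated gene in the table")
    rows = []
    for (term_id, term_name, category), sub in ann.groupby(
        ["term_id", "term_name", "category"], sort=True
    ):
        genes = set(sub["gene"])
        k1 = len(genes & g1)
        k2 = len(genes & g2)
        if k1 == 0 and k2 == 0:
            continue
        z, p = two_proportion_ztest(k1, mapped1, k2, mapped2)
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "category": category,
                "count1": k1,
                "percent1": 100.0 * k1 / mapped1,
                "count2": k2,
                "percent2": 100.0 * k2 / mapped2,
                "z": z,
                "p": p,
                "n1_mapped": mapped1,
                "n1_total": len(g1),
                "n2_mapped": mapped2,
                "n2_total": len(g2),
            }
        )
    if not rows:
        raise ValueError("no term annotates any gene of either group")
    df = pd.DataFrame(rows)
    df["abs_z"] = df["z"].abs()
    df = (
        df.sort_values(["p", "abs_z", "term_id"], ascending=[True, False, True])
        .drop(columns="abs_z")
        .reset_index(drop=True)
    )
    if include_bh:
        df["p_bh"] = stats.false_discovery_control(df["p"], method="bh")
    return df


def write_enrichment(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
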