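"""Breed-specific categorical enrichment via one-sided Fisher exact tests.

For each site in a gene, each breed in turn is contrasted against the
pooled other breeds for each category observed at the site (amino-acid
mode) or for the fixed categories {Y, N} (Indel-presence mode). The 2x2
table counts haplotypes:

                     focal category   other categories
    focal breed            a                 b
    other breeds           c                 d

and the test is one-sided with alternative odds ratio > 1 (the category is
over-represented in the focal breed). Amino-acid mode therefore runs
3 * k * n tests for a 3-breed panel (k = categories observed per site,
n = sites); Indel mode runs 3 * 2 * n. Bonferroni correction is applied
over all tests in the chosen scope (per gene by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .datatypes import SiteTestRecord


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail Fisher exact p: P(X >= a) for hypergeometric X with the
    table's margins."""
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("counts must be non-negative integers")
    if a + b + c + d < 1:
        raise ValueError("empty table")
    # X ~ Hypergeom(M=total, n=row1 total, N=col1 total)
    return float(hypergeom.sf(a - 1, a + b + c + d, a + b, a + c))


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def enumerate_tests(
    matrix: pd.DataFrame,
    mode: str = "aa",
    gene_id: str = "gene",
    breeds: list[str] | None = None,
) -> list[SiteTestRecord]:
    """Run every (breed, category, site) Fisher test for one gene.

    ``matrix`` rows are haplotypes with a ``breed`` column; remaining
    columns are sites (category labels). aa mode tests each category
    observed at the site; indel mode tests the fixed categories Y and N.
    """
    if "breed" not in matrix.columns:
        raise ValueError("matrix must have a 'breed' column")
    breed_col = matrix["breed"].to_numpy()
    present = list(dict.fromkeys(breed_col))
    if breeds is None:
        breeds = present
    missing = [b for b in breeds if b not in present]
    if missing:
        raise ValueError(f"breed(s) {', '.join(missing)} absent from input")
    if len(breeds) < 2:
        raise ValueError("need at least 2 breeds")
    site_cols = [col for col in matrix.columns if col != "breed"]

    records: list[SiteTestRecord] = []
    for site_idx, col in enumerate(site_cols, start=1):
        values = matrix[col].to_numpy()
        if mode == "aa":
            categories = sorted(set(values))
        elif mode == "indel":
            bad = set(values) - {"Y", "N"}
            if bad:
                raise ValueError(f"indel mode expects Y/N categories, got {bad}")
            categories = ["Y", "N"]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for breed in breeds:
            in_breed = breed_col == breed
            for cat in categories:
                in_cat = values == cat
                a = int(np.sum(in_breed & in_cat))
                b = int(np.sum(in_breed & ~in_cat))
                c = int(np.sum(~in_breed & in_cat))
                d = int(np.sum(~in_breed & ~in_cat))
                records.append(
                    SiteTestRecord(
                        gene_id=gene_id,
                        site=site_idx,
                        breed=breed,
                        category=str(cat),
                        a=a,
                        b=b,
                        c=c,
                        d=d,
                        odds_ratio=_odds_ratio(a, b, c, d),
                        p_raw=fisher_one_sided(a, b, c, d),
                    )
                )
    return records


def bonferroni(
    records: list[SiteTestRecord],
    alpha: float = 0.05,
    scope: str = "per_gene",
) -> dict[str, float]:
    """Bonferroni-adjust p-values in place; returns per-scope cutoffs.

    p_bonf = min(1, m * p_raw); significant iff p_raw < alpha / m, where m
    counts tests in the scope (all tests of the record's gene, or all
    records globally). The returned dict maps scope key ('*' for global)
    to the raw-p cutoff alpha/m, the value of the corrected significance
    line in per-site profile plots.
    """
    if scope == "global":
        groups: dict[str, list[SiteTestRecord]] = {"*": records}
    elif scope == "per_gene":
        groups = {}
        for r in records:
            groups.setdefault(r.gene_id, []).append(r)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    cutoffs: dict[str, float] = {}
    for key, rs in groups.items():
        m = len(rs)
        cutoffs[key] = alpha / m if m else float("nan")
        for r in rs:
            r.m_tests = m
            r.p_bonf = min(1.0, m * r.p_raw)
            r.significant = r.p_raw < alpha / m
    return cutoffs


def profile_table(
    records: list[SiteTestRecord], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-site -log10(p_raw) profile for one gene, ordered by site index.

    One row per test, with the nominal significance line (-log10 alpha)
    and the Bonferroni cutoff line (-log10 alpha/m) attached, ready for a
    per-gene line plot over sites.
    """
    genes = {r.gene_id for r in records}
    if len(genes) != 1:
        raise ValueError(f"profile_table expects one gene, got {sorted(genes)}")
    if any(r.m_tests is None for r in records):
        raise ValueError("run bonferroni() before building the profile")
    m = records[0].m_tests
    rows = [
        {
            "gene_id": r.gene_id,
            "site": r.site,
            "breed": r.breed,
            "category": r.category,
            "neg_log10_p": -np.log10(r.p_raw),
            "significant": r.significant,
        }
        for r in sorted(records, key=lambda r: (r.site, r.breed, r.category))
    ]
    df = pd.DataFrame(rows)
    df.attrs["nominal_line"] = -np.log10(alpha)
    df.attrs["bonferroni_line"] = -np.log10(alpha / m)
    df["nominal_line"] = -np.log10(alpha)
    df["bonferroni_line"] = -np.log10(alpha / m)
    return df


def read_site_matrix(path) -> pd.DataFrame:
    """Read a TSV site matrix (rows = haplotypes, 'breed' column + sites)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "breed" not in df.columns:
        raise ValueError(f"{path}: no 'breed' column")
    return df
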