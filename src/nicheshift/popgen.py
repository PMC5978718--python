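"""Clonal discrimination and ploidy filtering of multilocus genotypes.

In a haplodiplontic seaweed, field collections mix diploids, haploids
and clonal fragments of one genet. Phenotype analyses want one ramet
per unique diploid genet, so this module:

* calls ploidy from microsatellite data — a thallus is diploid iff at
  least one locus is heterozygous (homozygous-at-all-loci diploids are
  therefore called haploid; the rule is applied verbatim);
* computes ``pgen``, the Hardy-Weinberg probability of drawing a
  multilocus genotype (MLG) from population allele frequencies, and
  ``Psex``, the binomial-tail probability that an MLG observed n times
  in a sample of N arose from independent sexual events;
* drops haploids and, for repeated MLGs whose Psex falls below alpha,
  all ramets but the first.

Genotype tables are wide CSVs: ``population, thallus, <locus>_a1,
<locus>_a2, ...`` with 0/blank meaning a missing allele (haploids carry
a single allele per locus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

MIN_SHARED_LOCI = 5  # fewer mutually scored loci -> thalli not matchable


def locus_columns(df: pd.DataFrame) -> list[str]:
    """Locus names inferred from paired ``_a1``/``_a2`` columns."""
    loci = [c[:-3] for c in df.columns if c.endswith("_a1")]
    missing = [l for l in loci if f"{l}_a2" not in df.columns]
    if missing:
        raise ValueError(f"loci without an _a2 column: {missing}")
    if not loci:
        raise ValueError("no locus columns found")
    return loci


def _alleles(row, locus) -> tuple[int, int]:
    a1 = row[f"{locus}_a1"]
    a2 = row[f"{locus}_a2"]
    a1 = 0 if pd.isna(a1) else int(a1)
    a2 = 0 if pd.isna(a2) else int(a2)
    return a1, a2


def infer_ploidy(row, loci) -> str:
    """'diploid' iff >= 1 locus carries two distinct alleles, else 'haploid'."""
    scored = False
    for locus in loci:
        a1, a2 = _alleles(row, locus)
        if a1 or a2:
            scored = True
        if a1 and a2 and a1 != a2:
            return "diploid"
    if not scored:
        raise ValueError("unscorable genotype: all loci missing")
    return "haploid"


def allele_frequencies(pop_df: pd.DataFrame, loci=None,
                       dedupe_first: bool = True) -> dict[str, dict[int, float]]:
    """Per-locus relative allele frequencies from non-missing alleles.

    With ``dedupe_first`` (default), exact-duplicate MLGs are collapsed to
    one copy before counting, reducing clonal inflation of frequencies.
    """
    loci = loci or locus_columns(pop_df)
    df = pop_df
    if dedupe_first:
        df = df.drop_duplicates(subset=[c for l in loci for c in (f"{l}_a1", f"{l}_a2")])
    freqs: dict[str, dict[int, float]] = {}
    for locus in loci:
        alleles = pd.concat([df[f"{locus}_a1"], df[f"{locus}_a2"]])
        alleles = alleles[alleles.fillna(0) > 0].astype(int)
        counts = alleles.value_counts()
        total = counts.sum()
        freqs[locus] = {} if total == 0 else (counts / total).to_dict()
    return freqs


def pgen(row, freqs: dict[str, dict[int, float]], loci=None) -> float:
    """HWE probability of one diploid MLG: product of p^2 / 2pq over scored loci."""
    loci = loci if loci is not None else list(freqs)
    out = 1.0
    any_scored = False
    for locus in loci:
        a1, a2 = _alleles(row, locus)
        if not (a1 and a2):
            continue  # missing or haploid-scored locus skipped
        any_scored = True
        f = freqs[locus]
        if a1 not in f or a2 not in f:
            raise ValueError(f"allele {a1 if a1 not in f else a2} at {locus} "
                             "absent from frequency table")
        out *= f[a1] ** 2 if a1 == a2 else 2.0 * f[a1] * f[a2]
    if not any_scored:
        raise ValueError("no fully scored locus: pgen undefined")
    return out


def psex(pgen_value: float, n_observed: int, n_sampled: int) -> float:
    """P(an MLG recurs >= n times in N samples under independent sexual events).

    Binomial upper tail: sum_{j=n}^{N} C(N, j) pgen^j (1-pgen)^(N-j);
    monotone increasing in pgen.
    """
    if not (0 <= pgen_value <= 1):
        raise ValueError("pgen must be in [0, 1]")
    if not (1 <= n_observed <= n_sampled):
        raise ValueError("need 1 <= n_observed <= N_sampled")
    return float(binom.sf(n_observed - 1, n_sampled, pgen_value))


def mlg_match(row_a, row_b, loci) -> bool:
    """Same MLG over all mutually scored loci (>= MIN_SHARED_LOCI required)."""
    shared = 0
    for locus in loci:
        a = _alleles(row_a, locus)
        b = _alleles(row_b, locus)
        if not (a[0] and a[1] and b[0] and b[1]):
            continue
        shared += 1
        if tuple(sorted(a)) != tuple(sorted(b)):
            return False
    return shared >= MIN_SHARED_LOCI


@dataclass
class CloneReport:
    """Dedupe outcome: per-thallus calls plus per-population summaries."""

    thallus_table: pd.DataFrame    # population, thallus, mlg_id, ploidy, pgen, psex, keep, reason
    population_summary: pd.DataFrame  # population, n_thalli, n_haploid, n_clone_dropped, n_unique_genets
    retained: list[str]


def dedupe(genotypes: pd.DataFrame, alpha: float = 0.05,
           dedupe_freqs_first: bool = True) -> CloneReport:
    """Drop haploids and significant clonal replicates, population by population.

    Thalli sharing an identical MLG over mutually scored loci are grouped;
    within a group, if Psex < ``alpha`` the repeats are flagged clones and
    all but the first (input order) dropped. Haploids are always dropped.
    """
    if len(genotypes) == 0:
        import warnings
        warnings.warn("empty genotype table", stacklevel=2)
        return CloneReport(pd.DataFrame(), pd.DataFrame(), [])
    loci = locus_columns(genotypes)
    rows, summaries = [], []
    for pop, pop_df in genotypes.groupby("population", sort=False):
        ploidy = {idx: infer_ploidy(pop_df.loc[idx], loci) for idx in pop_df.index}
        dips = [idx for idx in pop_df.index if ploidy[idx] == "diploid"]
        # group diploids into MLGs by first-match against group representatives
        groups: list[list] = []
        for idx in dips:
            for grp in groups:
                if mlg_match(pop_df.loc[grp[0]], pop_df.loc[idx], loci):
                    grp.append(idx)
                    break
            else:
                groups.append([idx])
        freqs = allele_frequencies(pop_df.loc[dips] if dips else pop_df, loci,
                                   dedupe_first=dedupe_freqs_first)
        n_sampled = len(pop_df)
        n_clone_dropped = 0
        for g_i, grp in enumerate(groups):
            rep = pop_df.loc[grp[0]]
            pg = pgen(rep, freqs, loci)
            ps = psex(pg, len(grp), n_sampled) if len(grp) > 1 else np.nan
            is_clonal = len(grp) > 1 and ps < alpha
            for j, idx in enumerate(grp):
                keep = not (is_clonal and j > 0)
                reason = "" if keep else "clone"
                if not keep:
                    n_clone_dropped += 1
                rows.append([pop, pop_df.loc[idx, "thallus"], f"{pop}-MLG{g_i + 1:02d}",
                             "diploid", pg, ps, keep, reason])
        for idx in pop_df.index:
            if ploidy[idx] == "haploid":
                rows.append([pop, pop_df.loc[idx, "thallus"], "", "haploid",
                             np.nan, np.nan, False, "haploid"])
        summaries.append([pop, len(pop_df), sum(1 for i in pop_df.index if ploidy[i] == "haploid"),
                          n_clone_dropped, len(groups)])
    table = pd.DataFrame(rows, columns=["population", "thallus", "mlg_id", "ploidy",
                                        "pgen", "psex", "keep", "reason"])
    # restore input order
    order = {t: i for i, t in enumerate(genotypes["thallus"])}
    table = table.sort_values("thallus", key=lambda s: s.map(order)).reset_index(drop=True)
    summary = pd.DataFrame(summaries, columns=["population", "n_thalli", "n_haploid",
                                               "n_clone_dropped", "n_unique_genets"])
    retained = table.loc[table.keep, "thallus"].tolist()
    return CloneReport(table, summary, retained)
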