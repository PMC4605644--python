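"""Univariate marker statistics: differential expression, literature
direction concordance and target-gene enrichment.

Differential expression uses the pooled-variance (Student's) two-sample
t-test per feature with Holm's step-down multiple-testing adjustment; the
fold change is the group mean difference on the normalized (generalized-log)
scale, i.e. approximately a log-ratio. Enrichment of signature-miRNA target
genes within disease susceptibility loci uses Fisher's exact test with
Bonferroni correction; the gene/locus annotations are user-supplied tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def t_test_per_feature(matrix: pd.DataFrame, group_a: list[str], group_b: list[str]) -> pd.DataFrame:
    """Pooled-variance two-sided t-test per feature, A vs B.

    Returns a table with columns fc (mean(A) - mean(B)), t, p, padj (Holm).
    A zero pooled variance yields p=1 for equal means and p=0 (flagged in
    ``degenerate``) for unequal means.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 samples per group")
    A = matrix[group_a].to_numpy(dtype=float)
    B = matrix[group_b].to_numpy(dtype=float)
    na, nb = A.shape[1], B.shape[1]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    va = A.var(axis=1, ddof=1)
    vb = B.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    fc = ma - mb
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, np.where(fc == 0, 0.0, np.inf * np.sign(fc)), fc / se)
    df = na + nb - 2
    p = np.where(
        degenerate,
        np.where(fc == 0, 1.0, 0.0),
        2 * stats.t.sf(np.abs(np.where(degenerate, 0.0, t)), df),
    )
    out = pd.DataFrame(
        {"fc": fc, "t": t, "p": p, "degenerate": degenerate}, index=matrix.index
    )
    out["padj"] = holm_adjust(out["p"].to_numpy())
    return out


def holm_adjust(p) -> np.ndarray:
    """Holm's sequential (step-down) Bonferroni adjustment."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def bonferroni_adjust(p, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment with an explicit test count m (default len(p))."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, m * p)


def direction_concordance(de: pd.DataFrame, literature: pd.DataFrame) -> dict:
    """Percent of literature effect directions matched by the fc sign.

    ``literature`` has columns feature, direction in {'up', 'down'}. Features
    absent from the DE table are excluded and counted. Direction is compared
    on the sign of fc only, irrespective of significance.
    """
    dir_map = {"up": 1, "down": -1}
    overlap = [f for f in literature["feature"] if f in de.index]
    missing = [f for f in literature["feature"] if f not in de.index]
    if not overlap:
        raise ValueError("no overlap between literature set and DE table")
    lit = literature.set_index("feature")
    agree = sum(
        1
        for f in overlap
        if np.sign(de.loc[f, "fc"]) == dir_map[str(lit.loc[f, "direction"]).lower()]
    )
    return {
        "percent_agreement": 100.0 * agree / len(overlap),
        "n_overlap": len(overlap),
        "n_missing": len(missing),
        "missing_features": missing,
    }


@dataclass
class EnrichmentResult:
    """2x2 enrichment of signature-miRNA targets within risk loci.

    C_r / C: signature targets at risk / non-risk loci; R_r / R: the same for
    the remaining (non-signature) targets; N = C_r + C + R_r + R.
    """

    C_r: int
    C: int
    R_r: int
    R: int
    odds_ratio: float
    p: float
    padj: float | None = None

    @property
    def N(self) -> int:
        return self.C_r + self.C + self.R_r + self.R


def fisher_enrichment(
    signature_targets: set[str], all_targets: set[str], risk_genes: set[str]
) -> EnrichmentResult:
    """Two-sided Fisher's exact test for risk-locus overrepresentation among
    the targets of a signature's miRNAs, against all validated targets.

    The odds ratio uses the Haldane 0.5 correction when a cell is zero.
    """
    signature_targets = set(signature_targets)
    all_targets = set(all_targets)
    if not signature_targets or not all_targets:
        raise ValueError("target sets must be nonempty")
    if not signature_targets <= all_targets:
        raise ValueError("signature targets must be a subset of all validated targets")
    rest = all_targets - signature_targets
    c_r = len(signature_targets & risk_genes)
    c = len(signature_targets - risk_genes)
    r_r = len(rest & risk_genes)
    r = len(rest - risk_genes)
    _, p = stats.fisher_exact([[c_r, c], [r_r, r]], alternative="two-sided")
    if min(c_r, c, r_r, r) == 0:
        oddsr = ((c_r + 0.5) * (r + 0.5)) / ((c + 0.5) * (r_r + 0.5))
    else:
        oddsr = (c_r * r) / (c * r_r)
    return EnrichmentResult(C_r=c_r, C=c, R_r=r_r, R=r, odds_ratio=float(oddsr), p=float(p))


def enrichment_table(
    signatures: dict[str, set[str]],
    mirna_targets: dict[str, set[str]],
    locus_sets: dict[str, set[str]],
) -> pd.DataFrame:
    """Fisher enrichment of every signature against every locus set, with
    Bonferroni adjustment over all tests performed.

    ``signatures`` maps signature name -> miRNA ids; ``mirna_targets`` maps
    miRNA id -> target genes; ``locus_sets`` maps locus-set name -> genes.
    """
    all_targets = set().union(*mirna_targets.values()) if mirna_targets else set()
    rows = []
    for sig_name, mirnas in signatures.items():
        targets = set().union(*(mirna_targets.get(m, set()) for m in mirnas))
        if not targets:
            continue
        for locus_name, genes in locus_sets.items():
            res = fisher_enrichment(targets, all_targets, genes)
            rows.append(
                {
                    "signature": sig_name,
                    "locus_set": locus_name,
                    "C_r": res.C_r,
                    "C": res.C,
                    "R_r": res.R_r,
                    "R": res.R,
                    "N": res.N,
                    "odds_ratio": res.odds_ratio,
                    "p": res.p,
                }
            )
    tab = pd.DataFrame(rows)
    if not tab.empty:
        tab["padj"] = bonferroni_adjust(tab["p"].to_numpy(), m=len(tab))
    return tab
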