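"""Classify fibrinogen-regulated genes by citrullination responsiveness and
score gene-set enrichment per module.

The design has three treatment conditions — vehicle, fibrinogen, and
citrullinated fibrinogen — applied to monocytes from two or more donors.
Genes concordantly moved by fibrinogen in every donor are split into three
modules: module 1 (up by fibrinogen, unaffected by citrullination),
module 2 (moved by fibrinogen in either direction but significantly
reversed under citrullinated fibrinogen), and module 3 (down by
fibrinogen, unaffected by citrullination).  Genes whose citrullination
response concordantly continues in the fibrinogen direction are left
unclassified ("none"), as are discordant genes.

Enrichment uses the weighted Kolmogorov-Smirnov running-sum statistic on a
ranked gene list, with gene-label permutations for the normalized
enrichment score (NES) and FDR q-value — phenotype permutation is not an
option with two donors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DEGCall",
    "ModuleLabel",
    "EnrichmentResult",
    "call_degs",
    "classify_modules",
    "enrichment_score",
    "permutation_nes",
    "enrichment_table",
    "read_expression",
    "read_gmt",
    "module_counts",
    "CONDITIONS",
]

CONDITIONS = ("vehicle", "fibrinogen", "cit_fibrinogen")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples log2 expression with a (condition, donor) column
    MultiIndex.  Every donor must carry all three conditions."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        cols = self.values.columns
        if not isinstance(cols, pd.MultiIndex) or cols.nlevels != 2:
            raise ValueError("columns must be a (condition, donor) MultiIndex")
        unknown = set(cols.get_level_values(0)) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions {sorted(unknown)}")
        for donor in self.donors:
            have = {c for c, d in cols if d == donor}
            missing = set(CONDITIONS) - have
            if missing:
                raise ValueError(f"donor {donor!r} missing conditions {sorted(missing)}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def donors(self) -> list:
        return sorted(set(self.values.columns.get_level_values(1)))

    def delta(self, cond_a: str, cond_b: str) -> pd.DataFrame:
        """Per-donor log2 difference cond_a - cond_b (genes x donors)."""
        a = self.values[cond_a]
        b = self.values[cond_b]
        return a[self.donors] - b[self.donors]


@dataclass(frozen=True)
class DEGCall:
    gene: str
    per_donor: tuple[str, ...]  # UP/NC/DN per donor, donor-sorted order
    concordant: str  # UP, DN, NC, or discordant


@dataclass(frozen=True)
class ModuleLabel:
    gene: str
    module: str  # module1, module2, module3, or none


def _direction(delta: float, threshold: float) -> str:
    if delta >= threshold:
        return "UP"
    if delta <= -threshold:
        return "DN"
    return "NC"


def call_degs(expr: ExpressionMatrix, fc_threshold: float = 1.0) -> list[DEGCall]:
    """Per-donor UP/NC/DN of fibrinogen vs vehicle at a log2 fold-change
    threshold, with strict all-donor concordance."""
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    deltas = expr.delta("fibrinogen", "vehicle")
    out: list[DEGCall] = []
    for gene, row in deltas.iterrows():
        dirs = tuple(_direction(v, fc_threshold) for v in row)
        uniq = set(dirs)
        if uniq == {"UP"}:
            conc = "UP"
        elif uniq == {"DN"}:
            conc = "DN"
        elif uniq == {"NC"}:
            conc = "NC"
        else:
            conc = "discordant"
        out.append(DEGCall(gene=str(gene), per_donor=dirs, concordant=conc))
    return out


def classify_modules(
    degs: Sequence[DEGCall],
    expr: ExpressionMatrix,
    reversal_threshold: float = 1.0,
    majority_vote: bool = False,
) -> list[ModuleLabel]:
    """Assign module1/2/3/none from DEG calls and the citrullination
    response (cit_fibrinogen - fibrinogen).

    A reversal is declared when the citrullination delta opposes the
    concordant fibrinogen direction by at least ``reversal_threshold`` in
    every donor (or a majority, when ``majority_vote``).  Genes whose
    citrullination delta concordantly continues in the fibrinogen
    direction at threshold are unclassified: the design treats such genes
    as outside the three-module scheme.  Non-DEGs and discordant genes are
    ``none``.  Output order follows ``degs``; the labels are invariant to
    gene and donor ordering.
    """
    if reversal_threshold <= 0:
        raise ValueError("reversal_threshold must be positive")
    cit = expr.delta("cit_fibrinogen", "fibrinogen")
    n_donors = cit.shape[1]
    need = (n_donors // 2 + 1) if majority_vote else n_donors
    out: list[ModuleLabel] = []
    for deg in degs:
        if deg.concordant not in ("UP", "DN"):
            out.append(ModuleLabel(deg.gene, "none"))
            continue
        if deg.gene not in cit.index:
            raise KeyError(f"DEG gene {deg.gene!r} absent from expression matrix")
        row = cit.loc[deg.gene]
        sign = 1.0 if deg.concordant == "UP" else -1.0
        n_reversed = int((sign * row <= -reversal_threshold).sum())
        n_same = int((sign * row >= reversal_threshold).sum())
        if n_reversed >= need:
            module = "module2"
        elif n_same >= need:
            module = "none"
        elif deg.concordant == "UP":
            module = "module1"
        else:
            module = "module3"
        out.append(ModuleLabel(deg.gene, module))
    return out


def module_counts(labels: Iterable[ModuleLabel]) -> dict[str, int]:
    counts = {"module1": 0, "module2": 0, "module3": 0, "none": 0}
    for lab in labels:
        counts[lab.module] += 1
    return counts


# --- gene-set enrichment ----------------------------------------------------


@dataclass(frozen=True)
class EnrichmentResult:
    gene_set: str
    es: float
    nes: float
    p_value: float
    fdr_q: float
    n_permutations: int
    warning: str | None = None


def enrichment_score(
    ranked_genes: Sequence[tuple[str, float]],
    gene_set: Iterable[str],
    weight: float = 1.0,
) -> float:
    """Weighted KS running-sum enrichment score on a ranked list.

    ``ranked_genes`` is (gene, score) ordered from most up- to most
    down-ranked.  Hits advance the running sum by |score|^weight
    (normalized), misses retreat by 1/(N - Nh); the ES is the maximal
    deviation from zero, signed: positive for concentration at the top.
    |ES| <= 1 by construction.
    """
    genes = [g for g, _ in ranked_genes]
    scores = np.asarray([s for _, s in ranked_genes], dtype=float)
    member_set = set(gene_set)
    members = np.asarray([g in member_set for g in genes])
    n_hit = int(members.sum())
    n = len(genes)
    if n_hit == 0:
        raise ValueError("gene set has empty intersection with the ranked list")
    if n_hit == n:
        raise ValueError("gene set covers the whole ranked list")
    return _es_from_members(scores, members, weight)


def _es_from_members(scores: np.ndarray, members: np.ndarray, weight: float) -> float:
    n = len(scores)
    n_hit = int(members.sum())
    hit_w = np.where(members, np.abs(scores) ** weight, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all member scores are zero (possible at weight>0); fall back to
        # equal hit weights so the statistic stays defined
        hit_w = members.astype(float)
        denom = float(n_hit)
    steps = hit_w / denom - (~members) / (n - n_hit)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def permutation_nes(
    es: float,
    ranked_genes: Sequence[tuple[str, float]],
    gene_set: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> EnrichmentResult:
    """Normalize an enrichment score against a gene-label permutation null.

    The null redraws the gene-set labels uniformly over the ranked list
    (set size preserved); NES = ES / mean(|null ES| of matching sign).
    The p-value and FDR q follow the standard positive/negative-tail
    procedure on the null NES distribution; with a single gene set the
    q-value reduces to the matching-sign tail probability.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    genes = [g for g, _ in ranked_genes]
    scores = np.asarray([s for _, s in ranked_genes], dtype=float)
    member_set = set(gene_set) & set(genes)
    n_hit = len(member_set)
    if n_hit == 0:
        raise ValueError("gene set has empty intersection with the ranked list")
    rng = np.random.default_rng(seed)
    n = len(genes)
    null_es = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=n_hit, replace=False)
        members = np.zeros(n, dtype=bool)
        members[idx] = True
        null_es[i] = _es_from_members(scores, members, weight)
    warning = None
    same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
    two_sided_fallback = len(same_sign) < 10
    if two_sided_fallback:
        warning = (
            f"only {len(same_sign)} same-sign null scores out of {n_perm}; "
            "falling back to a two-sided |ES| tail"
        )
        same_sign = np.abs(null_es)
    mean_null = float(np.mean(np.abs(same_sign)))
    nes = es / mean_null if mean_null > 0 else 0.0
    pos_null = null_es[null_es >= 0]
    neg_null = null_es[null_es < 0]
    null_nes = np.concatenate(
        [
            pos_null / np.mean(pos_null) if len(pos_null) else pos_null,
            neg_null / np.mean(np.abs(neg_null)) if len(neg_null) else neg_null,
        ]
    )
    # tail fractions are conditional on the matching sign, per the standard
    # positive/negative-tail procedure
    if two_sided_fallback:
        p = float(np.mean(np.abs(null_es) >= abs(es)))
        q = float(np.mean(np.abs(null_nes) >= abs(nes)))
    elif es >= 0:
        p = float(np.mean(same_sign >= es)) if es != 0 else 1.0
        pos = null_nes[null_nes >= 0]
        q = float(np.mean(pos >= nes)) if len(pos) else 1.0
    else:
        p = float(np.mean(same_sign <= es))
        neg = null_nes[null_nes < 0]
        q = float(np.mean(neg <= nes)) if len(neg) else 1.0
    return EnrichmentResult(
        gene_set="",
        es=float(es),
        nes=float(nes),
        p_value=p,
        fdr_q=min(1.0, q),
        n_permutations=n_perm,
        warning=warning,
    )


def enrichment_table(
    ranked_genes: Sequence[tuple[str, float]],
    gene_sets: Mapping[str, Iterable[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Score several gene sets and report ES / NES / p / FDR-q per set.

    The q-values here re-use each set's own permutation null (sets of
    different sizes are not pooled); for a single set this coincides with
    :func:`permutation_nes`.
    """
    rows = []
    for i, (name, members) in enumerate(gene_sets.items()):
        es = enrichment_score(ranked_genes, members, weight)
        res = permutation_nes(
            es, ranked_genes, members, n_perm=n_perm, seed=seed + i, weight=weight
        )
        rows.append(
            {
                "gene_set": name,
                "es": res.es,
                "nes": res.nes,
                "p_value": res.p_value,
                "fdr_q": res.fdr_q,
                "n_permutations": res.n_permutations,
            }
        )
    return pd.DataFrame(rows).set_index("gene_set")


# --- I/O --------------------------------------------------------------------


def read_expression(expr_path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Load genes x samples expression (CSV/TSV, first column = gene) plus
    a sample annotation sidecar with columns sample, condition, donor."""
    sep = "\t" if str(expr_path).endswith((".tsv", ".txt")) else ","
    values = pd.read_csv(expr_path, sep=sep, index_col=0)
    dsep = "\t" if str(design_path).endswith((".tsv", ".txt")) else ","
    design = pd.read_csv(design_path, sep=dsep)
    design = design.set_index("sample")
    missing = set(values.columns) - set(design.index)
    if missing:
        raise ValueError(f"samples without design rows: {sorted(missing)}")
    tuples = [
        (design.loc[s, "condition"], design.loc[s, "donor"]) for s in values.columns
    ]
    values.columns = pd.MultiIndex.from_tuples(tuples, names=["condition", "donor"])
    return ExpressionMatrix(values)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return sets


def labels_to_tsv(labels: Sequence[ModuleLabel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tmodule\n")
        for lab in labels:
            fh.write(f"{lab.gene}\t{lab.module}\n")
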