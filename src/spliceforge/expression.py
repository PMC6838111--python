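"""Read filtering, interval counting, FPKM, qPCR ratios, and DE statistics.

The differential-expression machinery is a pooled two-sided exact binomial
test with library-size offsets plus Benjamini-Hochberg correction — a
deliberately simple, exactly testable replacement for negative-binomial
packages.  A feature is called differentially expressed when its normalized
fold change exceeds twofold in either direction AND its adjusted p-value is
at most 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gene_model import GeneModel, Interval
from .simulate import SimRead

Q_PASS = 30          # a base passes at quality >= 30
MIN_PASS_FRACTION = 0.70


# ---------------------------------------------------------------------------
# quality filtering

@dataclass
class FilterReport:
    kept: int
    trimmed: int
    removed: int


def quality_filter(
    reads: list[SimRead], q_pass: int = Q_PASS, min_fraction: float = MIN_PASS_FRACTION
) -> tuple[list[SimRead], FilterReport]:
    """Trim sub-Q30 3' ends, then drop reads with <70% passing bases.

    The pass fraction is computed after trimming; reads empty after trimming
    are removed.  Quality strings must match sequence length.
    """
    kept: list[SimRead] = []
    trimmed = removed = 0
    for r in reads:
        if len(r.qual) != len(r.seq):
            raise ValueError(f"quality length mismatch for {r.name}")
        end = len(r.qual)
        while end > 0 and r.qual[end - 1] < q_pass:
            end -= 1
        if end == 0:
            removed += 1
            continue
        qual = r.qual[:end]
        frac = sum(q >= q_pass for q in qual) / len(qual)
        if frac < min_fraction:
            removed += 1
            continue
        if end < len(r.qual):
            trimmed += 1
            r = SimRead(
                name=r.name,
                seq=r.seq[:end],
                qual=qual,
                variant=r.variant,
                tx_start=r.tx_start,
                genome_intervals=_clip_footprint(r.genome_intervals, end),
            )
        kept.append(r)
    return kept, FilterReport(kept=len(kept), trimmed=trimmed, removed=removed)


def _clip_footprint(intervals: list[Interval], length: int) -> list[Interval]:
    out: list[Interval] = []
    remaining = length
    for iv in intervals:
        take = min(len(iv), remaining)
        if take > 0:
            out.append(Interval(iv.start, iv.start + take))
        remaining -= take
        if remaining <= 0:
            break
    return out


# ---------------------------------------------------------------------------
# counting

@dataclass
class CountsTable:
    """Feature x sample counts with lengths, conditions, library sizes.

    ``features`` carries one row per feature: gene_id, kind ("gene" or
    "intron"), intron_index, length (nt).
    """

    counts: pd.DataFrame
    features: pd.DataFrame
    conditions: pd.Series
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.features["length"] <= 0).any():
            raise ValueError("feature lengths must be positive")
        assigned = self.counts.sum(axis=0)
        if (self.library_sizes + 1e-9 < assigned).any():
            raise ValueError("library size below column sum of assigned counts")


def count_features(
    reads_by_sample: dict[str, list[SimRead]],
    model: GeneModel,
    conditions: dict[str, str],
    mode: str = "strict",
) -> tuple[CountsTable, pd.Series]:
    """Assign reads to exon-union/intron features and count per sample.

    In ``strict`` mode (default) a read counts toward the gene's exon-region
    feature when its whole genomic footprint lies within the exon union,
    toward intron ``i`` when it lies entirely within that intron, and is
    left unassigned ("ambiguous") otherwise — including reads straddling an
    exon/intron boundary.  In ``overlap`` mode a read not contained in the
    exon union counts toward the single intron it overlaps (ambiguous when
    it overlaps several); this is the mode to use when introns are shorter
    than the read length, where strict containment is impossible.
    """
    if mode not in ("strict", "overlap"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    introns = model.introns
    gene = model.gene_id
    feature_ids = [gene] + [f"{gene}:intron{i + 1}" for i in range(len(introns))]
    exon_len = sum(len(e) for e in model.exons)
    lengths = [exon_len] + [len(iv) for iv in introns]

    counts = {}
    ambiguous = {}
    for sample, reads in reads_by_sample.items():
        col = dict.fromkeys(feature_ids, 0)
        amb = 0
        for r in reads:
            fp = r.genome_intervals
            if all(
                any(e.contains(iv) for e in model.exons) for iv in fp
            ):
                col[gene] += 1
                continue
            if mode == "strict":
                hits = [
                    i for i, intron in enumerate(introns)
                    if all(intron.contains(iv) for iv in fp)
                ]
            else:
                hits = [
                    i for i, intron in enumerate(introns)
                    if any(iv.start < intron.end and intron.start < iv.end for iv in fp)
                ]
            hit = hits[0] if len(hits) == 1 else None
            if hit is not None:
                col[f"{gene}:intron{hit + 1}"] += 1
            else:
                amb += 1
        counts[sample] = [col[f] for f in feature_ids]
        ambiguous[sample] = amb
    df = pd.DataFrame(counts, index=feature_ids)
    features = pd.DataFrame(
        {
            "gene_id": gene,
            "kind": ["gene"] + ["intron"] * len(introns),
            "intron_index": [None] + list(range(len(introns))),
            "length": lengths,
        },
        index=feature_ids,
    )
    lib = df.sum(axis=0) + pd.Series(ambiguous)
    table = CountsTable(
        counts=df,
        features=features,
        conditions=pd.Series(conditions),
        library_sizes=lib,
    )
    return table, pd.Series(ambiguous, name="ambiguous")


# ---------------------------------------------------------------------------
# normalization and simple measures

def fpkm(count: float, feature_length_nt: float, library_size: float) -> float:
    """Fragments per kilobase of feature per million mapped reads."""
    if feature_length_nt <= 0 or library_size <= 0:
        raise ValueError("feature length and library size must be positive")
    return count / (feature_length_nt / 1000.0) / (library_size / 1e6)


def relative_qpcr(cwp_abs: float, s18_abs: float) -> float:
    """Relative expression: (target / 18S reference) x 1000."""
    if s18_abs <= 0:
        raise ValueError("reference absolute expression must be positive")
    return (cwp_abs / s18_abs) * 1000.0


# ---------------------------------------------------------------------------
# exact test + FDR

def exact_count_test(
    count_a: int, count_b: int, lib_a: float, lib_b: float
) -> float:
    """Two-sided exact binomial test of pooled counts with library offsets.

    Under the null, ``count_a`` is Binomial(count_a + count_b,
    lib_a / (lib_a + lib_b)).  Two-sidedness sums the probabilities of all
    outcomes no more likely than the observed one.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    total = count_a + count_b
    if total == 0:
        return 1.0
    p = lib_a / (lib_a + lib_b)
    return stats.binomtest(count_a, total, p, alternative="two-sided").pvalue


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Per-feature differential-expression outcomes."""

    table: pd.DataFrame  # log2fc, p_value, p_adj, is_de, direction

    @property
    def de_features(self) -> set[str]:
        return set(self.table.index[self.table["is_de"]])


def call_de(
    table: CountsTable,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    kind: str | None = None,
) -> DEResult:
    """Exact-test DE calls between the two conditions of a counts table.

    Replicate counts and library sizes are pooled per condition.  The
    normalized fold change uses a 0.5 pseudocount on zero counts; a feature
    is DE when the fold change exceeds ``fc_threshold`` in either direction
    and the BH-adjusted p-value is at most ``alpha``.
    """
    conds = sorted(set(table.conditions))
    if len(conds) != 2:
        raise ValueError(f"need exactly two conditions, got {conds}")
    a_samples = table.conditions[table.conditions == conds[0]].index
    b_samples = table.conditions[table.conditions == conds[1]].index
    counts = table.counts
    if kind is not None:
        counts = counts.loc[table.features["kind"] == kind]
    ca = counts[a_samples].sum(axis=1)
    cb = counts[b_samples].sum(axis=1)
    la = float(table.library_sizes[a_samples].sum())
    lb = float(table.library_sizes[b_samples].sum())
    if la <= 0 or lb <= 0:
        raise ValueError("missing or zero library sizes")
    pvals = np.array(
        [exact_count_test(int(x), int(y), la, lb) for x, y in zip(ca, cb)]
    )
    padj = bh_adjust(pvals)
    na = ca.where(ca > 0, 0.5) / la
    nb = cb.where(cb > 0, 0.5) / lb
    log2fc = np.log2(na / nb)
    is_de = ((log2fc > np.log2(fc_threshold)) | (log2fc < -np.log2(fc_threshold))) & (
        padj <= alpha
    )
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": pvals,
            "p_adj": padj,
            "is_de": is_de,
            "direction": np.where(log2fc > 0, "up", "down"),
        },
        index=counts.index,
    )
    return DEResult(table=out)


def differential_intron_genes(
    table: CountsTable, fc_threshold: float = 2.0, alpha: float = 0.05
) -> set[str]:
    """Genes with at least one differentially expressed intron region."""
    intron_mask = table.features["kind"] == "intron"
    if not intron_mask.any():
        return set()
    res = call_de(table, fc_threshold=fc_threshold, alpha=alpha, kind="intron")
    flagged = res.de_features
    return set(table.features.loc[list(flagged), "gene_id"])


def overlap_summary(de_genes: set[str], intron_genes: set[str]) -> dict[str, int]:
    """Venn counts between expression-level and intron-level gene sets."""
    both = de_genes & intron_genes
    return {
        "de_only": len(de_genes - both),
        "intron_only": len(intron_genes - both),
        "both": len(both),
    }
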