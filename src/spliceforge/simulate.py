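"""Synthetic data: genes, reads, count tables, clone tallies, qPCR levels.

Everything the pipeline consumes can be generated here under a single seed,
with ground truth carried alongside so that downstream statistics are tested
against known answers.  Two gene builders are provided:

* :func:`make_gene` — a randomized gene whose every intron is U2-compliant
  by construction (planted donor/acceptor/branchpoint/poly-U features).
* :func:`build_cwp_like_gene` — a fixed, fully deterministic reconstruction
  of a cuticular-water-permeability-like locus: 4 exons / 3 introns with one
  alternative 5' donor (inside exon 1) and one alternative 3' acceptor
  (inside exon 3), engineered so the seven catalogued isoforms have the
  published transcript and protein lengths.  The sequence is synthetic; no
  genomic accession underlies it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gene_model import GeneModel, Interval
from .splice import (
    SpliceEvent,
    TranscriptVariant,
    alt_3_acceptor,
    alt_5_donor,
    apply_events,
    exon_skip,
    intron_retention,
)
from .u2 import validate_all

# ---------------------------------------------------------------------------
# configuration

#: Variant mixture magnitudes for the two temperature conditions.  The "high"
#: condition carries 38% of the functional full-length isoform and 29% of the
#: alt-acceptor isoform; under "low" these shift to 51% and 10%, with the
#: minor isoforms nearly unchanged.
DEFAULT_PROPORTIONS = {
    "high": {
        "VAR1": 0.38, "VAR2": 0.10, "VAR3": 0.29, "VAR4": 0.05,
        "VAR5": 0.08, "VAR6": 0.04, "VAR7": 0.06,
    },
    "low": {
        "VAR1": 0.51, "VAR2": 0.10, "VAR3": 0.10, "VAR4": 0.05,
        "VAR5": 0.12, "VAR6": 0.04, "VAR7": 0.08,
    },
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults emulate the source study's design: a 4-exon/3-intron gene,
    single-end 50 bp reads, two temperature conditions with two sequencing
    replicates each, ~100 clones per condition in three replications, and a
    tenfold planted qPCR induction.
    """

    seed: int = 0
    n_exons: int = 4
    exon_length_range: tuple[int, int] = (90, 300)
    intron_length_range: tuple[int, int] = (60, 120)
    ua_fraction_target: float = 0.65
    read_length: int = 50
    depth: int = 10000
    low_quality_fraction: float = 0.1
    # negative-binomial count model
    n_genes: int = 2000
    n_reps: int = 2
    nb_mean_log_mu: float = 4.5
    nb_mean_log_sigma: float = 1.0
    nb_dispersion: float = 0.1
    de_fraction: float = 0.05
    de_fold_change: float = 4.0
    intron_fraction_of_gene: float = 0.1
    intron_de_fraction: float = 0.05
    # clone counting
    n_clones: int = 100
    n_clone_replicates: int = 3
    gel_noise_sd_frac: float = 0.01
    proportions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(p) for c, p in DEFAULT_PROPORTIONS.items()}
    )
    # qPCR absolute levels (target, reference) per condition
    qpcr_levels: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"low": (20.0, 10000.0), "high": (2.0, 10000.0)}
    )
    qpcr_noise_cv: float = 0.15

    def __post_init__(self) -> None:
        for cond, props in self.proportions.items():
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(f"proportions for {cond!r} do not sum to 1")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """A named, reproducible substream of the global seed."""
        import zlib

        key = zlib.crc32(stream.encode()) % 2**31
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# randomized U2-compliant gene

_EXON_ALPHABET = np.array(list("ACGT"))


def _plant_u2_intron(rng: np.random.Generator, length: int, ua_target: float) -> str:
    """An intron passing all five U2 rules, with a unique in-window branchpoint.

    Layout: GTAAGT | filler | CTGAC | A-run | TTTT | TGCAG.  Together with
    the acceptor's leading T the poly-U tract is exactly 5 T, so a single
    substitution inside it abolishes rule 5.
    """
    length = max(length, 45)
    d = int(rng.integers(35, min(66, length - 6)))  # branchpoint distance
    filler_a_len = length - d - 6
    filler_b_len = d - 14
    for _ in range(200):
        # filler skewed toward A/T for U/A richness; T runs upstream of the
        # branchpoint are harmless for rule 5
        filler = "".join(
            rng.choice(list("AT"), p=[0.55, 0.45])
            if rng.random() < max(ua_target + 0.15, 0.7)
            else rng.choice(list("GC"))
            for _ in range(filler_a_len)
        )
        intron = "GTAAGT" + filler + "CTGAC" + "A" * filler_b_len + "TTTT" + "TGCAG"
        assert len(intron) == length
        if _branchpoints_of(intron) == [d]:
            return intron
    raise RuntimeError("could not build a compliant intron; relax length constraints")


def _branchpoints_of(intron: str) -> list[int]:
    iu = {"Y": "CT", "R": "AG"}
    hits = []
    for s in range(len(intron) - 4):
        w = intron[s : s + 5]
        if (w[0] in iu["Y"] and w[1] == "T" and w[2] in iu["R"] and w[3] == "A"
                and w[4] in iu["Y"]):
            dist = len(intron) - s
            if 30 <= dist <= 70:
                hits.append(dist)
    return sorted(hits)


def make_gene(cfg: SimConfig) -> GeneModel:
    """A random gene whose every intron passes the full U2 rule set.

    Exon 2 (when present) gets a length not divisible by 3, so skipping it
    shifts the reading frame.
    """
    rng = cfg.rng("gene")
    lo, hi = cfg.exon_length_range
    exon_lens = [int(rng.integers(lo, hi + 1)) for _ in range(cfg.n_exons)]
    if cfg.n_exons >= 3 and exon_lens[1] % 3 == 0:
        exon_lens[1] += 1
    ilo, ihi = cfg.intron_length_range
    intron_lens = [
        max(45, int(rng.integers(ilo, ihi + 1))) for _ in range(cfg.n_exons - 1)
    ]
    parts: list[str] = []
    exons: list[Interval] = []
    pos = 0
    for i, el in enumerate(exon_lens):
        exon = "".join(rng.choice(_EXON_ALPHABET, size=el))
        # keep the exon/intron junction consensus bases on the exon side
        if i < len(intron_lens):
            exon = exon[:-2] + "AG"
        if i > 0:
            exon = "GT" + exon[2:]
        parts.append(exon)
        exons.append(Interval(pos, pos + el))
        pos += el
        if i < len(intron_lens):
            parts.append(_plant_u2_intron(rng, intron_lens[i], cfg.ua_fraction_target))
            pos += intron_lens[i]
    model = GeneModel(gene_id="synth_gene", seq="".join(parts), exons=exons)
    bad = [r.intron_index for r in validate_all(model) if not r.u2_type]
    if bad:  # pragma: no cover - generator contract
        raise RuntimeError(f"generated introns {bad} fail U2 validation")
    return model


# ---------------------------------------------------------------------------
# the deterministic cwp-like locus

# Coordinate plan (all 0-based, transcription orientation):
#   exon 1 [0,261)    26 nt 5'UTR, ATG at 26, coding phase ends mid-codon
#   intron 1 [261,359)
#   exon 2 [359,599)  opens with an in-frame stop for the shifted frame
#   intron 2 [599,634)  35 nt, retained in VAR2/VAR7
#   exon 3 [634,924)
#   intron 3 [924,1025)
#   exon 4 [1025,1088)  canonical stop at offset 45, 15 nt 3'UTR
# Alternative sites: 5' donor of intron 1 at 245 (inside exon 1, at a codon
# boundary 219 nt into the CDS); 3' acceptor of intron 2 at 822 (188 nt into
# exon 3).  These place every published quantity: isoform lengths 854 / 889 /
# 666 / 650 / 838 / 410 / 873 nt, proteins 270 / 187 / 185 / 73 / 73 / 122 /
# 73 aa, premature stops in exon 3 (VAR2, VAR3) and exon 2 (VAR4/5/7), and a
# frame-restoring exon-2 skip for VAR6.

ALT5_DONOR_SITE = 245
ALT3_ACCEPTOR_SITE = 822


def _cwp_exon1() -> str:
    utr5 = "CT" * 13
    codons = ["GCC"] * 77          # aa 2..78 of the full-length protein
    codons[71] = "GAC"             # aa 73: last residue shared by all isoforms
    codons[72] = "CAC"             # aa 74: differs from every truncated isoform
    codons[76] = "GCA"             # aa 78: exon must end with AG (donor consensus)
    return utr5 + "ATG" + "".join(codons) + "G"


def _cwp_exon2() -> str:
    # TAA is in frame for transcripts using the alternative 5' donor: their
    # 73-aa reading frame terminates on the first exon-2 codon.
    body = "".join("CCG"[i % 3] for i in range(3, 238))
    return "TAA" + body + "AG"


def _cwp_exon3() -> str:
    seq = ["CCG"[i % 3] for i in range(290)]
    seq[0:3] = "ATC"          # breaks the acceptor-side GT consensus on purpose
    seq[51:54] = "TAA"        # premature stop for the intron-2-retaining frame
    seq[188:191] = "TCC"      # first codon after the alternative 3' acceptor
    seq[268:271] = "TAA"      # premature stop for the alt-acceptor frame
    seq[288:290] = "AG"
    return "".join(seq)


def _cwp_exon4() -> str:
    return "GTC" + "GCC" * 14 + "TGA" + "CTCTCTCTCTCTCTC"


def _cwp_intron(filler_len: int, polyt_len: int) -> str:
    filler = "".join("TA"[k % 2] for k in range(filler_len))
    return "GTAAGT" + filler + "CTGAC" + "T" * polyt_len + "TGCAG"


def build_cwp_like_gene() -> GeneModel:
    """The deterministic cwp-like reference locus (synthetic reconstruction)."""
    exons_seq = [_cwp_exon1(), _cwp_exon2(), _cwp_exon3(), _cwp_exon4()]
    introns_seq = [
        _cwp_intron(47, 35),                               # 98 nt
        "GTAAGTTGAC" + "T" * 20 + "TGCAG",                 # 35 nt
        _cwp_intron(50, 35),                               # 101 nt
    ]
    parts = []
    exons = []
    pos = 0
    for i, ex in enumerate(exons_seq):
        parts.append(ex)
        exons.append(Interval(pos, pos + len(ex)))
        pos += len(ex)
        if i < len(introns_seq):
            parts.append(introns_seq[i])
            pos += len(introns_seq[i])
    return GeneModel(gene_id="cwp_like", seq="".join(parts), exons=exons)


def cwp_catalog() -> list[tuple[str, list[SpliceEvent]]]:
    """The seven catalogued event sets, named in the conventional order."""
    a3 = alt_3_acceptor(1, ALT3_ACCEPTOR_SITE)
    a5 = alt_5_donor(0, ALT5_DONOR_SITE)
    return [
        ("VAR1", []),
        ("VAR2", [intron_retention(1)]),
        ("VAR3", [a3]),
        ("VAR4", [a3, a5]),
        ("VAR5", [a5]),
        ("VAR6", [a3, a5, exon_skip(1)]),
        ("VAR7", [intron_retention(1), a5]),
    ]


# ---------------------------------------------------------------------------
# reads

@dataclass
class SimRead:
    """A single-end read with per-base qualities and its true origin."""

    name: str
    seq: str
    qual: list[int]
    variant: str
    tx_start: int
    genome_intervals: list[Interval]


def _tx_to_genome(variant: TranscriptVariant, start: int, length: int) -> list[Interval]:
    """Genomic footprint of transcript interval [start, start+length)."""
    out: list[Interval] = []
    remaining = length
    offset = start
    for seg in variant.segments:
        if offset >= len(seg):
            offset -= len(seg)
            continue
        take = min(len(seg) - offset, remaining)
        out.append(Interval(seg.start + offset, seg.start + offset + take))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    if remaining:
        raise IndexError("read extends past transcript end")
    return out


def make_reads(
    model: GeneModel,
    variants: list[TranscriptVariant],
    mixture: dict[str, float],
    cfg: SimConfig,
    stream: str = "reads",
) -> list[SimRead]:
    """Uniform-start SE reads from a transcript mixture, with truth labels.

    Read counts are multinomial(depth, mixture); a ``low_quality_fraction``
    of reads carries interspersed sub-Q30 bases so they fail the 70% quality
    filter.  Transcripts shorter than the read length are skipped with a
    warning.
    """
    import logging

    rng = cfg.rng(stream)
    by_name = {v.name: v for v in variants}
    usable = {}
    for name, p in mixture.items():
        if len(by_name[name].seq) < cfg.read_length:
            logging.getLogger(__name__).warning(
                "transcript %s shorter than read length; skipped", name
            )
            continue
        usable[name] = p
    total = sum(usable.values())
    names = sorted(usable)
    probs = np.array([usable[n] / total for n in names])
    counts = rng.multinomial(cfg.depth, probs)
    reads: list[SimRead] = []
    idx = 0
    for name, n in zip(names, counts):
        var = by_name[name]
        starts = rng.integers(0, len(var.seq) - cfg.read_length + 1, size=n)
        low_q = rng.random(n) < cfg.low_quality_fraction
        for s, bad in zip(starts, low_q):
            s = int(s)
            seq = var.seq[s : s + cfg.read_length]
            if bad:
                qual = [20 if i % 5 < 2 else 35 for i in range(cfg.read_length)]
            else:
                qual = [38] * cfg.read_length
            reads.append(
                SimRead(
                    name=f"read_{idx}",
                    seq=seq,
                    qual=qual,
                    variant=name,
                    tx_start=s,
                    genome_intervals=_tx_to_genome(var, s, cfg.read_length),
                )
            )
            idx += 1
    return reads


def write_fastq(reads: list[SimRead], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n")
            fh.write("".join(chr(q + 33) for q in r.qual) + "\n")


# ---------------------------------------------------------------------------
# count tables

def make_counts(cfg: SimConfig) -> tuple["CountsTable", pd.DataFrame]:
    """NB gene and intron counts for two conditions, with planted effects.

    Returns the counts table and a truth table (feature, kind, true_log2fc,
    is_de).  DE genes get the configured fold change in condition A;
    intron-DE genes get the fold change on their intron feature only.
    """
    from .expression import CountsTable

    rng = cfg.rng("counts")
    n = cfg.n_genes
    genes = [f"gene_{i:05d}" for i in range(n)]
    base_mean = np.exp(rng.normal(cfg.nb_mean_log_mu, cfg.nb_mean_log_sigma, size=n))
    is_de = rng.random(n) < cfg.de_fraction
    is_intron_de = (~is_de) & (rng.random(n) < cfg.intron_de_fraction)
    fc = np.where(is_de, cfg.de_fold_change, 1.0)
    intron_fc = np.where(is_intron_de, cfg.de_fold_change, 1.0)

    samples = []
    conditions = []
    for cond in ("A", "B"):
        for rep in range(1, cfg.n_reps + 1):
            samples.append(f"{cond}{rep}")
            conditions.append(cond)

    def nb_draw(mean: np.ndarray) -> np.ndarray:
        r = 1.0 / cfg.nb_dispersion
        p = r / (r + mean)
        return rng.negative_binomial(r, p)

    rows = {}
    lengths = {}
    meta = {}
    for j, g in enumerate(genes):
        gene_counts = []
        intron_counts = []
        for cond in conditions:
            mu = base_mean[j] * (fc[j] if cond == "A" else 1.0)
            gene_counts.append(nb_draw(np.array([mu]))[0])
            imu = base_mean[j] * cfg.intron_fraction_of_gene * (
                intron_fc[j] if cond == "A" else 1.0
            )
            intron_counts.append(nb_draw(np.array([imu]))[0])
        rows[g] = gene_counts
        rows[f"{g}:intron1"] = intron_counts
        lengths[g] = 1000
        lengths[f"{g}:intron1"] = 300
        meta[g] = (g, "gene", None)
        meta[f"{g}:intron1"] = (g, "intron", 0)

    counts = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    features = pd.DataFrame(
        [meta[f] for f in counts.index],
        index=counts.index,
        columns=["gene_id", "kind", "intron_index"],
    )
    features["length"] = [lengths[f] for f in counts.index]
    table = CountsTable(
        counts=counts,
        features=features,
        conditions=pd.Series(conditions, index=samples),
        library_sizes=counts.sum(axis=0),
    )
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "true_gene_log2fc": np.log2(fc),
            "is_de": is_de,
            "true_intron_log2fc": np.log2(intron_fc),
            "is_intron_de": is_intron_de,
        }
    )
    return table, truth


# ---------------------------------------------------------------------------
# clones and qPCR

def make_clones(
    cfg: SimConfig, variant_lengths: dict[str, int] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multinomial clone tallies per condition, plus per-clone insert sizes.

    Returns ``(counts, inserts)``: counts has one row per condition x
    replicate x variant; inserts lists each clone with its gel-measured
    insert length (variant length + Gaussian noise, sd = 1% of length by
    default) and its true identity.
    """
    rng = cfg.rng("clones")
    if variant_lengths is None:
        model = build_cwp_like_gene()
        variant_lengths = {
            name: len(apply_events(model, evs, name=name).seq)
            for name, evs in cwp_catalog()
        }
    count_rows = []
    insert_rows = []
    clone_id = 0
    for cond in sorted(cfg.proportions):
        props = cfg.proportions[cond]
        names = sorted(props)
        p = np.array([props[n] for n in names])
        for rep in range(1, cfg.n_clone_replicates + 1):
            tally = rng.multinomial(cfg.n_clones, p)
            for name, k in zip(names, tally):
                count_rows.append(
                    {"condition": cond, "replicate": rep, "variant": name, "count": int(k)}
                )
                true_len = variant_lengths[name]
                noise = rng.normal(0, cfg.gel_noise_sd_frac * true_len, size=k)
                for delta in noise:
                    insert_rows.append(
                        {
                            "clone_id": f"clone_{clone_id:05d}",
                            "condition": cond,
                            "replicate": rep,
                            "insert_length": float(true_len + delta),
                            "true_variant": name,
                        }
                    )
                    clone_id += 1
    return pd.DataFrame(count_rows), pd.DataFrame(insert_rows)


def make_qpcr(cfg: SimConfig, n_reps: int = 3) -> pd.DataFrame:
    """Absolute target/reference qPCR levels with lognormal noise."""
    rng = cfg.rng("qpcr")
    sigma = np.sqrt(np.log(1 + cfg.qpcr_noise_cv**2))
    rows = []
    for cond, (cwp, s18) in sorted(cfg.qpcr_levels.items()):
        for rep in range(1, n_reps + 1):
            rows.append(
                {
                    "condition": cond,
                    "replicate": rep,
                    "CWP_abs": cwp * rng.lognormal(-sigma**2 / 2, sigma),
                    "S18_abs": s18 * rng.lognormal(-sigma**2 / 2, sigma),
                }
            )
    return pd.DataFrame(rows)
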