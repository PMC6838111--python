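"""End-to-end orchestration: simulate, splice, ORF, U2, counts, DE, clones.

Every stage writes plain files into the run directory so any stage can be
re-run or inspected standalone, and a machine-readable ``summary.json``
collects the variant table, U2 reports, DE/intron-DE overlap, and clone
proportions.  The configuration and seed are echoed for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import pandas as pd

from . import __version__
from .clones import clone_counts_from_tallies, proportion_shift_test, proportions_ci
from .expression import (
    call_de,
    count_features,
    differential_intron_genes,
    overlap_summary,
    quality_filter,
    relative_qpcr,
)
from .gene_model import write_gene_model
from .orf import find_orf, locate_stop_exon, shared_termini
from .simulate import (
    SimConfig,
    build_cwp_like_gene,
    cwp_catalog,
    make_clones,
    make_counts,
    make_qpcr,
    make_reads,
    write_fastq,
)
from .splice import enumerate_variants, resplice, save_catalog
from .u2 import validate_all

log = logging.getLogger(__name__)


def run_pipeline(out_dir: str, cfg: SimConfig | None = None) -> dict:
    """Run the full synthetic study and return the summary dict."""
    cfg = cfg or SimConfig()
    os.makedirs(out_dir, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {
            k: v for k, v in dataclasses.asdict(cfg).items() if not isinstance(v, dict)
        },
    }

    # --- gene, variants, ORFs, U2 ---------------------------------------
    model = build_cwp_like_gene()
    write_gene_model(model, os.path.join(out_dir, "gene.gff3"), os.path.join(out_dir, "gene.fa"))
    catalog = cwp_catalog()
    save_catalog(catalog, os.path.join(out_dir, "events.yaml"))
    variants = enumerate_variants(model, catalog)

    orf_rows = []
    proteins: dict[str, str] = {}
    with open(os.path.join(out_dir, "variants.fa"), "w") as fh:
        for v in variants:
            fh.write(f">{v.name}\n{v.seq}\n")
            orf = locate_stop_exon(v, find_orf(v.seq), model)
            proteins[v.name] = orf.protein
            orf_rows.append(
                {
                    "variant": v.name,
                    "length_nt": len(v.seq),
                    "orf_start": orf.start_nt,
                    "orf_end": orf.end_nt,
                    "length_aa": orf.length_aa,
                    "stop_exon": orf.stop_exon,
                    "premature": orf.premature,
                }
            )
    with open(os.path.join(out_dir, "proteins.fa"), "w") as fh:
        for name, prot in proteins.items():
            fh.write(f">{name}\n{prot}\n")
    variant_table = pd.DataFrame(orf_rows)
    variant_table.to_csv(os.path.join(out_dir, "variants.tsv"), sep="\t", index=False)
    summary["variants"] = variant_table.to_dict(orient="records")

    unique = {}
    for name, prot in proteins.items():
        unique.setdefault(prot, name)
    shared_all = shared_termini(proteins)
    summary["n_distinct_proteins"] = len(unique)
    summary["n_term_shared_aa"] = shared_all.n_term_shared_aa

    var2 = next(v for v in variants if v.name == "VAR2")
    summary["resplice_products_of_VAR2"] = sorted(
        p.name for p in resplice(var2, model, catalog)
    )

    u2 = validate_all(model)
    summary["u2_reports"] = [
        {
            "intron": r.intron_index,
            "u2_type": r.u2_type,
            "donor_ok": r.donor_ok,
            "acceptor_ok": r.acceptor_ok,
            "ua_fraction": round(r.ua_fraction, 4),
            "branchpoints": r.branchpoints,
            "polyu_ok": r.polyu_ok,
        }
        for r in u2
    ]

    # --- reads, filtering, counting ------------------------------------
    mixtures = cfg.proportions
    reads_by_sample = {}
    conditions = {}
    filter_stats = {}
    for cond in sorted(mixtures):
        reads = make_reads(model, variants, mixtures[cond], cfg, stream=f"reads_{cond}")
        write_fastq(reads, os.path.join(out_dir, f"reads_{cond}.fastq"))
        kept, rep = quality_filter(reads)
        filter_stats[cond] = dataclasses.asdict(rep)
        reads_by_sample[cond] = kept
        conditions[cond] = cond
    summary["quality_filter"] = filter_stats
    table, ambiguous = count_features(reads_by_sample, model, conditions, mode="overlap")
    table.counts.to_csv(os.path.join(out_dir, "cwp_feature_counts.tsv"), sep="\t")
    summary["cwp_intron_counts"] = {
        s: table.counts.loc[f"{model.gene_id}:intron2", s].item()
        for s in table.counts.columns
    }

    # --- genome-scale counts, DE, intron DE -----------------------------
    counts, truth = make_counts(cfg)
    counts.counts.to_csv(os.path.join(out_dir, "counts.tsv"), sep="\t")
    truth.to_csv(os.path.join(out_dir, "counts_truth.tsv"), sep="\t", index=False)
    de = call_de(counts, kind="gene")
    de.table.to_csv(os.path.join(out_dir, "de_results.tsv"), sep="\t")
    de_genes = {counts.features.loc[f, "gene_id"] for f in de.de_features}
    intron_genes = differential_intron_genes(counts)
    summary["de_overlap"] = overlap_summary(de_genes, intron_genes)

    # --- qPCR ------------------------------------------------------------
    qpcr = make_qpcr(cfg)
    qpcr["CWP_R"] = [
        relative_qpcr(c, s) for c, s in zip(qpcr["CWP_abs"], qpcr["S18_abs"])
    ]
    qpcr.to_csv(os.path.join(out_dir, "qpcr.tsv"), sep="\t", index=False)
    means = qpcr.groupby("condition")["CWP_R"].mean()
    summary["qpcr_CWP_R_means"] = {k: round(v, 3) for k, v in means.items()}
    if "low" in means and "high" in means and means["high"] > 0:
        summary["qpcr_fold_change_low_vs_high"] = round(means["low"] / means["high"], 2)

    # --- clones ----------------------------------------------------------
    tallies, inserts = make_clones(cfg)
    tallies.to_csv(os.path.join(out_dir, "clone_tallies.tsv"), sep="\t", index=False)
    inserts.to_csv(os.path.join(out_dir, "clone_inserts.tsv"), sep="\t", index=False)
    cc = clone_counts_from_tallies(tallies)
    props = proportions_ci(cc)
    props.to_csv(os.path.join(out_dir, "clone_proportions.tsv"), sep="\t", index=False)
    summary["clone_proportions"] = {
        cond: {
            r["variant"]: round(r["p_hat"], 4)
            for _, r in sub.iterrows()
        }
        for cond, sub in props.groupby("condition")
    }
    summary["proportion_shift_p"] = proportion_shift_test(cc)

    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    return summary
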