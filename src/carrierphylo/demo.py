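"""Self-contained synthetic demo bundle.

Writes a complete input set for the pipeline — per-taxon proteomes with
decoys, a tagged reference FASTA, the species tree, a supergroup table, a
domain seed alignment, and a ready configuration — plus the generator's
ground truth for comparison, all derived from one seed.
"""

from __future__ import annotations

import os

import yaml

from .io_formats import Alignment, SeqRecord, write_fasta, write_tsv
from .simulate import SimConfig, SimTruth, simulate_dataset

#: Supergroup labels cycled over the demo taxa (stand-ins for the
#: eukaryotic supergroups used to summarize ortholog counts).
DEMO_SUPERGROUPS = ("Amorphea", "TSAR", "Archaeplastida", "Discoba")


def reference_records(truth: SimTruth) -> list[SeqRecord]:
    """Anchor and outgroup references copied from a suitable taxon.

    The first taxon retaining at least one member of each class provides
    the reference complement; copies get ``REF_*`` ids so reference and
    candidate sequences never collide.
    """
    for taxon in truth.species_tree.leaf_names():
        a = [l for l, c in truth.clade_of.items()
             if c == "A" and l.startswith(taxon + "|")]
        b = [l for l, c in truth.clade_of.items()
             if c == "B" and l.startswith(taxon + "|")]
        outs = sorted(l for l, c in truth.clade_of.items()
                      if c.startswith("O") and l.startswith(taxon + "|"))
        if a and b and outs:
            refs = [SeqRecord("REF_A", truth.sequences[sorted(a)[0]].residues,
                              f"role=anchor_A source={sorted(a)[0]}"),
                    SeqRecord("REF_B", truth.sequences[sorted(b)[0]].residues,
                              f"role=anchor_B source={sorted(b)[0]}")]
            refs += [SeqRecord(f"REF_OUT{i + 1}", truth.sequences[o].residues,
                               f"role=outgroup source={o}")
                     for i, o in enumerate(outs)]
            return refs
    raise RuntimeError("no taxon retains all reference classes; reseed")


def make_demo(seed: int, outdir: str, cfg: SimConfig | None = None) -> str:
    """Write the demo bundle; returns the path of the ready config file."""
    cfg = cfg or SimConfig(seed=seed)
    truth = simulate_dataset(cfg)
    os.makedirs(outdir, exist_ok=True)

    proteome_dir = os.path.join(outdir, "proteomes")
    os.makedirs(proteome_dir, exist_ok=True)
    for taxon, seqs in sorted(truth.proteomes.items()):
        with open(os.path.join(proteome_dir, f"{taxon}.fasta"), "w") as fh:
            fh.write(write_fasta(seqs))

    refs = reference_records(truth)
    with open(os.path.join(outdir, "references.fasta"), "w") as fh:
        fh.write(write_fasta(refs))

    with open(os.path.join(outdir, "species_tree.nwk"), "w") as fh:
        fh.write(truth.species_tree.to_newick() + "\n")

    taxa = truth.species_tree.leaf_names()
    write_tsv(os.path.join(outdir, "grouping.tsv"), ("taxon", "supergroup"),
              ((t, DEMO_SUPERGROUPS[i % len(DEMO_SUPERGROUPS)])
               for i, t in enumerate(sorted(taxa))))

    # Domain seed: family rows of half the taxa from the true alignment —
    # a domain model needs a seed spanning the family's diversity.
    seed_taxa = set(taxa[:max(4, len(taxa) // 2)])
    seed_rows = [r for r in truth.alignment.rows
                 if r.id.split("|")[0] in seed_taxa]
    with open(os.path.join(outdir, "seed_alignment.fasta"), "w") as fh:
        fh.write(write_fasta(Alignment(seed_rows).rows))

    truth_dir = os.path.join(outdir, "truth")
    os.makedirs(truth_dir, exist_ok=True)
    write_tsv(os.path.join(truth_dir, "events.tsv"),
              ("class", "branch", "kind"),
              ((e.cls, e.branch, e.kind) for e in truth.events))
    write_tsv(os.path.join(truth_dir, "observable_changes.tsv"),
              ("branch", "class", "delta"),
              truth.observable_branch_changes())
    counts = truth.survivor_counts()
    write_tsv(os.path.join(truth_dir, "survivor_counts.tsv"),
              ("taxon", "A", "B", "other"),
              ((t, *counts.loc[t]) for t in counts.index))
    write_tsv(os.path.join(truth_dir, "site_labels.tsv"),
              ("column", "label"),
              enumerate(truth.site_labels))
    write_tsv(os.path.join(truth_dir, "clades.tsv"), ("gene", "clade"),
              sorted(truth.clade_of.items()))
    with open(os.path.join(truth_dir, "gene_tree.nwk"), "w") as fh:
        fh.write(truth.gene_tree.to_newick() + "\n")
    with open(os.path.join(truth_dir, "true_alignment.fasta"), "w") as fh:
        fh.write(write_fasta(truth.alignment.rows))

    config = {
        "proteomes_dir": "proteomes",
        "references": "references.fasta",
        "species_tree": "species_tree.nwk",
        "grouping": "grouping.tsv",
        "seed_alignment": "seed_alignment.fasta",
        "identity_threshold": 0.9,
        "entropy_threshold": 0.5,
        "support_min": 75.0,
        "min_coverage": 0.5,
        "model": "poisson",
        "rate_categories": 1,
        "bootstrap": 100,
        "seed": seed,
        "outdir": os.path.join(outdir, "results"),
    }
    config_path = os.path.join(outdir, "config.yaml")
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path
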