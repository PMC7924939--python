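"""End-to-end orchestration of the carrier-subfamily analysis.

Stages, each reading plain-file artifacts and writing new ones into the
output directory, so any stage can be rerun or replaced by an external
tool (a real HMMER scan, a real IQ-TREE run) at the file boundary:

    scan -> cluster -> screen -> align -> tree -> classify
         -> events -> conserve -> annotate

A manifest records a checksum per artifact plus the fully resolved
configuration; thresholds actually used are logged.  All randomness
derives from the single configured seed, and two runs with the same
configuration produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import conservation as cons
from . import domain_scan, duploss, msa, orthology, phylo, redundancy, structmap
from .io_formats import (Alignment, SeqRecord, parse_newick, read_alignment,
                         read_fasta, read_newick, read_pdb, write_fasta,
                         write_pdb, write_tsv)

log = logging.getLogger("carrierphylo")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    # inputs
    proteomes_dir: str
    references: str
    species_tree: str
    grouping: str
    seed_alignment: str
    alignment: str | None = None        # precomputed stage-2 alignment
    pdb: str | None = None
    # thresholds and model settings
    identity_threshold: float = 0.9
    entropy_threshold: float = 0.5
    support_min: float = 75.0
    min_coverage: float = 0.5
    model: str = "poisson"              # "poisson" | "lg"
    rate_categories: int = 1
    bootstrap: int = 100
    stage1_bootstrap: int = 0
    w_gain: float = 2.0
    w_loss: float = 1.0
    c_max: int = 4
    scan_fpr: float = 1e-3
    scan_null_size: int = 400
    site_panel: list[int] = field(
        default_factory=lambda: list(cons.DEFAULT_SITE_PANEL))
    pdb_chain: str = "A"
    pdb_offset: int = 0
    # run control
    seed: int = 0
    outdir: str = "results"

    def validate(self) -> None:
        for name in ("proteomes_dir", "references", "species_tree",
                     "grouping", "seed_alignment"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise PipelineError(f"missing input {name}: {path}")
        for name in ("alignment", "pdb"):
            path = getattr(self, name)
            if path and not os.path.exists(path):
                raise PipelineError(f"missing input {name}: {path}")
        if not 0 < self.identity_threshold <= 1:
            raise PipelineError("identity_threshold must be in (0, 1]")
        if self.model not in ("poisson", "lg"):
            raise PipelineError(f"unknown model {self.model!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = os.path.dirname(os.path.abspath(path))
        cfg = cls(**raw)
        for name in ("proteomes_dir", "references", "species_tree",
                     "grouping", "seed_alignment", "alignment", "pdb"):
            val = getattr(cfg, name)
            if val and not os.path.isabs(val):
                setattr(cfg, name, os.path.join(base, val))
        return cfg


class Pipeline:
    """Runs stages against a config; artifacts live under ``cfg.outdir``."""

    def __init__(self, cfg: PipelineConfig):
        cfg.validate()
        self.cfg = cfg
        os.makedirs(cfg.outdir, exist_ok=True)

    # -- helpers ----------------------------------------------------------
    def path(self, *parts: str) -> str:
        p = os.path.join(self.cfg.outdir, *parts)
        os.makedirs(os.path.dirname(p), exist_ok=True)
        return p

    def taxa(self) -> list[str]:
        files = sorted(f for f in os.listdir(self.cfg.proteomes_dir)
                       if f.endswith((".fasta", ".fa", ".faa")))
        if not files:
            raise PipelineError(
                f"no proteome FASTA files in {self.cfg.proteomes_dir}")
        return [os.path.splitext(f)[0] for f in files]

    def _proteome_file(self, taxon: str) -> str:
        for ext in (".fasta", ".fa", ".faa"):
            p = os.path.join(self.cfg.proteomes_dir, taxon + ext)
            if os.path.exists(p):
                return p
        raise PipelineError(f"no proteome file for taxon {taxon!r}")

    def references(self) -> orthology.ReferenceSet:
        return orthology.ReferenceSet.from_records(
            read_fasta(self.cfg.references))

    # -- stages -----------------------------------------------------------
    def stage_scan(self) -> None:
        cfg = self.cfg
        seed_aln = read_alignment(cfg.seed_alignment)
        profile = domain_scan.build_profile(seed_aln)
        pool = []
        for taxon in self.taxa():
            pool.extend(read_fasta(self._proteome_file(taxon)))
        null = domain_scan.composition_null(pool, cfg.scan_null_size,
                                            seed=cfg.seed + 101)
        profile.threshold = domain_scan.calibrate_threshold(
            profile, null, cfg.scan_fpr)
        log.info("domain scan: profile length %d, threshold %.2f bits "
                 "(FPR %.0e on %d-sequence null)", profile.length,
                 profile.threshold, cfg.scan_fpr, cfg.scan_null_size)
        for taxon in self.taxa():
            seqs = read_fasta(self._proteome_file(taxon))
            hits = domain_scan.filter_proteome(seqs, profile)
            ids = {h.seq_id for h in hits}
            write_tsv(self.path("hits", f"{taxon}.tsv"),
                      ("seq_id", "score", "start", "end", "pass"),
                      (h.as_row() for h in hits))
            with open(self.path("hits", f"{taxon}.fasta"), "w") as fh:
                fh.write(write_fasta([s for s in seqs if s.id in ids]))
            log.info("taxon %s: %d/%d sequences pass the domain scan",
                     taxon, len(hits), len(seqs))

    def stage_cluster(self) -> None:
        cfg = self.cfg
        log.info("redundancy clustering at identity >= %.2f",
                 cfg.identity_threshold)
        for taxon in self.taxa():
            seqs = read_fasta(self.path("hits", f"{taxon}.fasta"))
            if seqs:
                clusters = redundancy.greedy_cluster(seqs,
                                                     cfg.identity_threshold)
                reps = set(clusters.representatives)
                rows = clusters.rows()
            else:
                reps, rows = set(), []
            write_tsv(self.path("clusters", f"{taxon}.tsv"),
                      ("member_id", "representative_id", "identity"), rows)
            with open(self.path("reps", f"{taxon}.fasta"), "w") as fh:
                fh.write(write_fasta([s for s in seqs if s.id in reps]))

    def stage_screen(self) -> None:
        cfg = self.cfg
        refs = self.references()
        ref_ids = {r.id for r in refs.records()}
        hits_by_taxon = {}
        for taxon in self.taxa():
            seqs = read_fasta(self.path("reps", f"{taxon}.fasta"))
            hits_by_taxon[taxon] = [s for s in seqs if s.id not in ref_ids]
        screens = orthology.screen_candidates(hits_by_taxon, refs,
                                              cfg.support_min, logger=log)
        pooled: list[SeqRecord] = []
        for taxon in self.taxa():
            asg = screens[taxon]
            write_tsv(self.path("screen", f"{taxon}.tsv"),
                      ("candidate_id", "taxon", "label", "defining_support"),
                      asg.rows())
            keep = {orthology.A_LIKE, orthology.B_LIKE, orthology.OTHER_FAMILY}
            retained = [c for c, l in sorted(asg.labels.items()) if l in keep]
            seqs = {s.id: s for s in
                    read_fasta(self.path("reps", f"{taxon}.fasta"))}
            pooled.extend(seqs[c] for c in retained)
            log.info("taxon %s: %d candidates retained", taxon, len(retained))
        with open(self.path("candidates.fasta"), "w") as fh:
            fh.write(write_fasta(pooled))

    def stage_align(self) -> None:
        cfg = self.cfg
        if cfg.alignment:
            log.info("using externally provided alignment %s", cfg.alignment)
            aln = read_alignment(cfg.alignment)
        else:
            refs = self.references()
            cands = read_fasta(self.path("candidates.fasta"))
            seqs = cands + refs.records()
            if len(seqs) < 2:
                raise PipelineError("fewer than 2 sequences to align")
            aln = msa.progressive_align(seqs)
        with open(self.path("stage2_alignment.fasta"), "w") as fh:
            fh.write(write_fasta(aln.rows))

    def stage_tree(self) -> None:
        cfg = self.cfg
        aln = read_alignment(self.path("stage2_alignment.fasta"))
        tree = phylo.nj_builder(aln)
        if cfg.model == "lg" or cfg.rate_categories > 1:
            freqs = phylo.empirical_frequencies(aln)
            model = (phylo.lg_model(freqs, cfg.rate_categories)
                     if cfg.model == "lg"
                     else phylo.poisson_model(cfg.rate_categories))
            log.info("likelihood stage: %s model, %d rate categories, +F "
                     "empirical frequencies", cfg.model, cfg.rate_categories)
            tree, model, ll = phylo.optimize_numeric(aln, tree, model)
            tree, ll = phylo.nni_search(aln, tree, model)
            log.info("final log-likelihood %.3f", ll)
        if cfg.bootstrap > 0:
            log.info("bootstrap supports: %d replicates (distance builder)",
                     cfg.bootstrap)
            tree = phylo.bootstrap_support(aln, phylo.nj_builder,
                                           cfg.bootstrap, seed=cfg.seed + 202,
                                           target_tree=tree)
        with open(self.path("stage2_tree.nwk"), "w") as fh:
            fh.write(tree.to_newick() + "\n")

    def stage_classify(self) -> None:
        cfg = self.cfg
        refs = self.references()
        tree = read_newick(self.path("stage2_tree.nwk"))
        rooted = orthology.root_at_outgroup(tree, refs.outgroup_ids())
        asg = orthology.assign_clades(rooted, refs, cfg.support_min)
        asg.taxon = {cid: cid.split("|")[0] for cid in asg.labels}
        log.info("classification at support >= %.0f: %d A-like, %d B-like, "
                 "%d other-family, %d outside", cfg.support_min,
                 len(asg.of(orthology.A_LIKE)), len(asg.of(orthology.B_LIKE)),
                 len(asg.of(orthology.OTHER_FAMILY)),
                 len(asg.of(orthology.NON_FAMILY)))
        write_tsv(self.path("assignments.tsv"),
                  ("candidate_id", "taxon", "label", "defining_support"),
                  asg.rows())

    def _load_assignments(self) -> orthology.CladeAssignment:
        labels, support, taxon = {}, {}, {}
        with open(self.path("assignments.tsv")) as fh:
            next(fh)
            for line in fh:
                cid, tax, lab, sup = line.rstrip("\n").split("\t")
                labels[cid] = lab
                taxon[cid] = tax
                support[cid] = float(sup) if sup else None
        return orthology.CladeAssignment(labels, support, taxon)

    def stage_events(self) -> None:
        cfg = self.cfg
        asg = self._load_assignments()
        species = read_newick(cfg.species_tree)
        grouping = {}
        with open(cfg.grouping) as fh:
            next(fh)
            for line in fh:
                taxon, group = line.rstrip("\n").split("\t")
                grouping[taxon] = group
        counts = duploss.copy_number_matrix(asg, self.taxa(), grouping)
        # the founding duplication predates the root: one ancestral copy
        # of each focal class; other-family counts keep a free root
        events = duploss.sankoff_events(
            species, counts, cfg.w_gain, cfg.w_loss, cfg.c_max,
            root_state={orthology.A_LIKE: 1, orthology.B_LIKE: 1})
        log.info("reconciliation: cost %.1f (w_gain=%.0f, w_loss=%.0f, "
                 "c_max=%d), %d event branches", events.total_cost,
                 cfg.w_gain, cfg.w_loss, cfg.c_max, len(events.events))
        write_tsv(self.path("copy_numbers.tsv"),
                  ("taxon", *duploss.CLASSES),
                  ((t, *counts.counts.loc[t]) for t in counts.taxa))
        write_tsv(self.path("events.tsv"),
                  ("branch", "class", "duplications", "losses"),
                  events.rows())
        write_tsv(self.path("ancestral_states.tsv"),
                  ("node", *duploss.CLASSES),
                  ((n, *(st[c] for c in duploss.CLASSES))
                   for n, st in events.ancestral.items()))
        means = duploss.supergroup_means(counts, grouping)
        write_tsv(self.path("supergroup_means.tsv"),
                  ("supergroup", *duploss.CLASSES),
                  ((g, *(f"{v:.3f}" for v in means.loc[g]))
                   for g in means.index))

    def stage_conserve(self) -> None:
        cfg = self.cfg
        refs = self.references()
        aln = read_alignment(self.path("stage2_alignment.fasta"))
        asg = self._load_assignments()
        clades = {refs.anchor_a.id: "A", refs.anchor_b.id: "B"}
        for r in refs.outgroup:
            clades[r.id] = "out"
        for cid, lab in asg.labels.items():
            clades[cid] = {"A_like": "A", "B_like": "B"}.get(lab, "other")
        # conservation is computed on the subfamily rows only
        keep = [rid for rid in aln.ids() if clades.get(rid) in ("A", "B")]
        sub = aln.subset(keep).drop_allgap_columns()
        table = cons.entropy_profile(sub, refs.anchor_a.id,
                                     {rid: clades[rid] for rid in keep})
        table = cons.classify_positions(table, cfg.entropy_threshold,
                                        cfg.min_coverage)
        log.info("conservation: entropy threshold %.2f bits, coverage >= "
                 "%.2f; %d positions, %d shared, %d A-specific, %d "
                 "B-specific", cfg.entropy_threshold, cfg.min_coverage,
                 len(table), (table.category == cons.SHARED).sum(),
                 (table.category == cons.A_SPECIFIC).sum(),
                 (table.category == cons.B_SPECIFIC).sum())
        table.to_csv(self.path("conservation.tsv"), sep="\t", index=False,
                     float_format="%.4f")
        panel = [p for p in cfg.site_panel
                 if p <= len(refs.anchor_a.ungapped())]
        if panel:
            states = cons.extract_site_states(
                sub, refs.anchor_a.id, panel,
                {rid: clades[rid] for rid in keep})
            states.to_csv(self.path("site_states.tsv"), sep="\t", index=False)

    def stage_annotate(self) -> None:
        cfg = self.cfg
        if not cfg.pdb:
            log.info("no structure model configured; skipping annotation")
            return
        import pandas as pd
        model = read_pdb(cfg.pdb)
        table = pd.read_csv(self.path("conservation.tsv"), sep="\t")
        ann = {int(r.ref_pos): float(r.H_cladeA)
               for r in table.itertuples() if pd.notna(r.H_cladeA)}
        annotated = structmap.annotate_structure(model, ann, cfg.pdb_chain,
                                                 cfg.pdb_offset)
        with open(self.path("annotated.pdb"), "w") as fh:
            fh.write(write_pdb(annotated))

    # -- orchestration ----------------------------------------------------
    STAGES = ("scan", "cluster", "screen", "align", "tree", "classify",
              "events", "conserve", "annotate")

    def run(self, stages: tuple[str, ...] = STAGES) -> None:
        for name in stages:
            log.info("=== stage %s ===", name)
            getattr(self, f"stage_{name}")()
        self.write_manifest()

    def write_manifest(self) -> None:
        entries = {}
        for dirpath, _, files in os.walk(self.cfg.outdir):
            for f in sorted(files):
                if f in ("manifest.json", "run.log"):
                    continue
                full = os.path.join(dirpath, f)
                rel = os.path.relpath(full, self.cfg.outdir)
                with open(full, "rb") as fh:
                    entries[rel] = hashlib.sha256(fh.read()).hexdigest()
        manifest = {"artifacts": dict(sorted(entries.items())),
                    "config": asdict(self.cfg)}
        with open(self.path("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(cfg: PipelineConfig) -> str:
    """Run every stage; returns the output directory."""
    Pipeline(cfg).run()
    return cfg.outdir
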