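"""End-to-end orchestration: scan -> align -> trim -> distances -> NJ ->
letters -> architectures -> motifs, with a reproducible report bundle.

Every stage writes its artifact into the output directory; a JSON run log
records all parameters and seeds so the bundle is a pure function of
(inputs, config).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core_io import (DomainAnnotationTable, ProteinRecord, read_fasta,
                      write_domain_annotations, write_fasta)
from .distance import distance_matrix, render_paper_table, write_distance_tsv
from .msa import (DomainAlignment, progressive_align, read_alignment_fasta,
                  trim_to_core, write_alignment_fasta)
from .motifs import (cytoplasmic_domain, find_literal_motifs, predict_tm,
                     scan_wc1_motif, user_topology)
from .njtree import bootstrap_tree, write_newick
from .nomenclature import (architecture_string, assign_letters,
                           classify_family, positional_refine,
                           reference_letters_from_alignment)
from .srcr_scan import build_domain_model, cysteine_pattern, scan_protein
from .synthetic_data import DEFAULT_ARCHITECTURES


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    input_fasta: str
    reference_alignment: str
    output_dir: str
    seed: int
    scan_threshold_fraction: float = 0.40
    support_threshold: float = 0.70
    distance_model: str = "p"
    deletion_mode: str = "pairwise"
    bootstrap_B: int = 200
    tm_mode: str = "predict"            # "predict" or path to a TSV of TM coords
    literal_motifs: tuple = ("YREM",)
    reference_architectures: tuple = DEFAULT_ARCHITECTURES

    def validate(self) -> None:
        for p in (self.input_fasta, self.reference_alignment):
            if not Path(p).exists():
                raise PipelineError(f"input path does not exist: {p}")
        if self.bootstrap_B > 0 and self.seed is None:
            raise PipelineError("seed required when bootstrap_B > 0")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a report dict and writes the bundle."""
    config.validate()
    records = read_fasta(config.input_fasta)
    reference = read_alignment_fasta(config.reference_alignment)
    ref_letters = reference_letters_from_alignment(reference)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- scan
    model = build_domain_model(reference)
    threshold = config.scan_threshold_fraction * model.self_score
    table = DomainAnnotationTable()
    hits_by_protein = {}
    for rec in records:
        hits = scan_protein(rec, model, score_threshold=threshold)
        hits_by_protein[rec.id] = hits
        for h in hits:
            missing, _, _ = cysteine_pattern(h)
            table.add(rec.id, h.domain_index, h.start, h.end, h.score,
                      missing_cysteines=missing)
    table.validate({r.id: len(r) for r in records})
    write_domain_annotations(table, out / "domains.tsv", "tsv")
    write_domain_annotations(table, out / "domains.gff3", "gff3")

    # --- align + trim
    seqs = [(lab, reference.ungapped(lab)) for lab in reference.labels]
    for rec in records:
        for h in hits_by_protein[rec.id]:
            seqs.append((f"{rec.id}|{h.domain_index}",
                         rec.sequence[h.start - 1:h.end]))
    if len(seqs) < 3:
        raise PipelineError("scan stage: fewer than 3 domain sequences")
    aln = progressive_align(seqs)
    core = trim_to_core(aln, model, reference_label=reference.labels[0])
    write_alignment_fasta(core, out / "core_alignment.fasta")

    # --- distances
    dmat = distance_matrix(core, model_tag=config.distance_model,
                           deletion_mode=config.deletion_mode,
                           B=config.bootstrap_B, seed=config.seed)
    write_distance_tsv(dmat, out / "distances.tsv", out / "distances_se.tsv")
    query_labels = [l for l in core.labels if l not in ref_letters]
    (out / "distance_table.txt").write_text(
        render_paper_table(dmat, query_labels, list(ref_letters)) + "\n")

    # --- tree with support
    tree = bootstrap_tree(core, model_tag=config.distance_model,
                          B=max(config.bootstrap_B, 100), seed=config.seed)
    write_newick(tree, out / "tree.nwk")

    # --- letters, architectures, family calls
    assignments = assign_letters(tree, ref_letters,
                                 threshold=config.support_threshold,
                                 query_order=query_labels)
    ref_archs = [a.split("-") for a in config.reference_architectures]
    assignments = positional_refine(assignments, ref_archs)
    arch_rows = []
    for rec in records:
        if not hits_by_protein[rec.id]:
            continue
        arch = architecture_string(rec.id, assignments)
        arch_rows.append({
            "protein_id": rec.id,
            "architecture": arch.render(),
            "family_call": classify_family(arch),
        })
    pd.DataFrame(
        [{"protein_id": a.protein_id, "domain_index": a.domain_index,
          "letter": a.letter, "method": a.method,
          "support": "" if a.support is None else f"{a.support:.3f}"}
         for a in assignments]
    ).to_csv(out / "assignments.tsv", sep="\t", index=False)
    pd.DataFrame(arch_rows).to_csv(out / "architectures.tsv", sep="\t",
                                   index=False)
    # fold letters back into the annotation table
    letter_of = {(a.protein_id, a.domain_index): a.letter
                 for a in assignments}
    for r in table.rows:
        r["letter"] = letter_of.get((r["protein_id"], r["domain_index"]),
                                    r["letter"])
    write_domain_annotations(table, out / "domains.tsv", "tsv")
    write_domain_annotations(table, out / "domains.gff3", "gff3")

    # --- motifs
    user_tm = None
    if config.tm_mode != "predict":
        df = pd.read_csv(config.tm_mode, sep="\t")
        user_tm = {}
        for _, row in df.iterrows():
            user_tm.setdefault(row["protein_id"], []).append(
                (int(row["start"]), int(row["end"])))
    motif_rows = []
    for rec in records:
        topo = (user_topology(rec, user_tm.get(rec.id, []))
                if user_tm is not None else predict_tm(rec))
        if topo.tm_regions:
            tail = cytoplasmic_domain(rec, topo)
        else:
            tail = ""
        hits = scan_wc1_motif(rec.sequence, rec.id, topo)
        hits += find_literal_motifs(rec.sequence, config.literal_motifs,
                                    rec.id, topo)
        for h in hits:
            motif_rows.append({
                "protein_id": h.protein_id, "position": h.position,
                "tetramer": h.tetramer, "pattern_id": h.pattern_id,
                "region": h.region,
                "tm_source": topo.source,
                "cytoplasmic_length": len(tail),
            })
    pd.DataFrame(motif_rows, columns=[
        "protein_id", "position", "tetramer", "pattern_id", "region",
        "tm_source", "cytoplasmic_length",
    ]).to_csv(out / "motifs.tsv", sep="\t", index=False)

    # --- run log
    log = {"version": __version__, "config": asdict(config),
           "n_records": len(records),
           "n_domains": len(table),
           "model_self_score": model.self_score,
           "scan_threshold": threshold}
    (out / "run_log.json").write_text(json.dumps(log, indent=2,
                                                 default=str) + "\n")
    return {
        "annotations": table,
        "alignment": core,
        "distances": dmat,
        "tree": tree,
        "assignments": assignments,
        "architectures": {r["protein_id"]: r["architecture"]
                          for r in arch_rows},
        "family_calls": {r["protein_id"]: r["family_call"]
                         for r in arch_rows},
        "motifs": motif_rows,
        "log": log,
    }
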