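"""End-to-end orchestration: decompose → homogeneity → variants → dN/dS → trees.

``run_all`` drives the full analysis from a :class:`RunConfig` and
writes a reproducible report bundle (gene model JSON, identity and
codon-usage TSVs, variant FASTA/TSV, newick trees, a plain-text
summary, and the resolved configuration).  Outputs contain no
timestamps, so two runs with the same config and inputs are
byte-identical; progress is logged to stderr.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import homogeneity as hmg
from . import repeat_array, seqio, selection, trees
from .alignment import align, write_aligned_fasta
from .variant_diagnosis import CloneSet, DiagnosisResult, diagnose

log = logging.getLogger("spidroin")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    gene_fasta: str
    out_dir: str
    clones_fasta: str | None = None
    clones_meta: str | None = None          # TSV: clone_id, individual, species, region
    domains_tsv: str | None = None
    cluster_threshold_pct: float = 95.0     # variant clustering, percent identical sites
    terminal_threshold: float = 0.5         # repeat/terminal boundary identity
    period_floor: float = 0.60              # minimum tandem self-similarity
    min_period: int = 30
    max_period: int | None = None
    gap_policy: str = hmg.PAIRWISE_DELETION
    ploidy: int = 2
    bootstrap_reps: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)


def _read_clone_sets(fasta: str, meta: str | None) -> list[CloneSet]:
    """Group clone records into CloneSets by (individual, region).

    Metadata comes from a sidecar TSV (clone_id, individual, species,
    region) or from structured headers ``>cloneID|species|individual|region``.
    """
    records = seqio.read_fasta(fasta)
    info: dict[str, tuple[str, str, str]] = {}
    if meta:
        for line in Path(meta).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cid, ind, sp, region = line.split("\t")[:4]
            info[cid] = (ind, sp, region)
    groups: dict[tuple[str, str, str], list[seqio.SeqRecord]] = {}
    for rec in records:
        if rec.id in info:
            ind, sp, region = info[rec.id]
            cid = rec.id
        elif "|" in rec.id:
            cid, sp, ind, region = rec.id.split("|")[:4]
        else:
            raise PipelineError(f"no metadata for clone {rec.id!r}")
        rec = seqio.SeqRecord(id=cid, residues=rec.residues, alphabet="nt")
        groups.setdefault((ind, sp, region), []).append(rec)
    return [CloneSet(individual=ind, species=sp, region=region, clones=clones)
            for (ind, sp, region), clones in sorted(groups.items())]


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the summary dict written to summary.txt."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(name)s %(levelname)s %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))
    summary: dict = {}

    gene_path = Path(config.gene_fasta)
    if not gene_path.exists():
        raise PipelineError(f"input FASTA not found: {gene_path}")

    # --- stage: decompose -------------------------------------------------
    log.info("stage decompose: %s", gene_path)
    gene = seqio.read_fasta(gene_path)[0]
    orf_iv = seqio.find_longest_orf(gene)
    orf = gene.slice(orf_iv, id=f"{gene.id}_ORF")
    protein = seqio.translate(orf)
    detection = repeat_array.detect_period(
        orf, min_period=config.min_period, max_period=config.max_period,
        score_floor=config.period_floor)
    model = repeat_array.segment_repeats(orf, detection.period_nt,
                                         terminal_threshold=config.terminal_threshold)
    model.to_json(out / "gene_model.json")
    regions = repeat_array.extract_regions(model, orf)
    seqio.write_fasta(regions.repeats, out / "repeat_units.fasta")
    summary.update({
        "orf_length_nt": len(orf_iv),
        "protein_length_aa": len(protein.residues.rstrip("*")),
        "period_nt": detection.period_nt,
        "period_score": round(detection.score, 4),
        "n_repeats": model.n_repeats,
        "first_repeat_len_nt": len(model.repeats[0]),
        "last_repeat_len_nt": len(model.repeats[-1]),
    })

    # --- stage: homogeneity ----------------------------------------------
    log.info("stage homogeneity: %d repeat units", model.n_repeats)
    rep_aln = align(regions.repeats, codon=True)
    write_aligned_fasta(rep_aln, out / "repeat_alignment.fasta")
    idm = hmg.identity_matrix(rep_aln, policy=config.gap_policy)
    idm.to_frame().to_csv(out / "repeat_identity.tsv", sep="\t")
    cons = hmg.consensus(rep_aln, id=f"{gene.id}_repeat_consensus")
    seqio.write_fasta([cons.record], out / "repeat_consensus.fasta")
    comp = hmg.composition(seqio.SeqRecord(
        id="p", residues=protein.residues.rstrip("*"), alphabet="aa"))
    usage = hmg.codon_usage(orf)
    usage.to_frame().to_csv(out / "codon_usage.tsv", sep="\t", index=False)
    gcw = usage.gcw_fraction()
    summary.update({
        "mean_repeat_identity_pct": round(idm.mean_offdiag(), 2),
        "first_repeat_identity_pct": round(idm.per_row_mean(rep_aln.ids[0]), 2),
        "last_repeat_identity_pct": round(idm.per_row_mean(rep_aln.ids[-1]), 2),
        "top_composition_pct": {aa: round(v, 2) for aa, v in
                                sorted(comp.items(), key=lambda kv: -kv[1])[:3]},
        "alanine_gcw_pct": None if gcw is None else round(100 * gcw, 2),
    })

    # --- stage: variants --------------------------------------------------
    diagnoses: list[DiagnosisResult] = []
    if config.clones_fasta:
        log.info("stage variants: %s", config.clones_fasta)
        clone_sets = _read_clone_sets(config.clones_fasta, config.clones_meta)
        all_variants = []
        rows = []
        for cs in clone_sets:
            result = diagnose(cs, threshold_pct=config.cluster_threshold_pct,
                              ploidy=config.ploidy)
            diagnoses.append(result)
            for v in result.variants:
                rec = seqio.SeqRecord(
                    id=f"{cs.species}|{cs.individual}|{cs.region}|{v.variant_id}",
                    residues=v.consensus.residues, alphabet="nt")
                all_variants.append(rec)
                rows.append("\t".join([cs.species, cs.individual, cs.region,
                                       v.variant_id, str(len(v.supporting_clones)),
                                       f"{v.within_identity_pct:.2f}"]))
        if all_variants:
            seqio.write_fasta(all_variants, out / "variants.fasta")
        header = "# species\tindividual\tregion\tvariant\tn_clones\twithin_identity_pct"
        (out / "variants.tsv").write_text("\n".join([header] + rows) + "\n")
        summary["variants"] = {
            f"{d.clone_set.species}/{d.clone_set.individual}/{d.clone_set.region}":
                {"n_variants": len(d.variants), "min_loci": d.min_loci}
            for d in diagnoses}

        # --- stage: dN/dS across variants per region ----------------------
        dnds_rows = []
        for region in ("N", "C", "repeat"):
            recs = [r for r in all_variants if r.id.split("|")[2] == region]
            if len(recs) < 2:
                continue
            aln = align(recs, codon=all(len(r) % 3 == 0 for r in recs))
            try:
                est = selection.region_dnds(aln, region=region)
            except selection.DnDsError as exc:
                log.warning("dN/dS undefined for region %s: %s", region, exc)
                continue
            dnds_rows.append("\t".join([
                region, f"{est.mean_dN:.4f}", f"{est.mean_dS:.4f}",
                "NA" if est.ratio_of_means is None else f"{est.ratio_of_means:.4f}",
                selection.classify(est.ratio_of_means)]))
            summary.setdefault("dnds", {})[region] = (
                None if est.ratio_of_means is None else round(est.ratio_of_means, 3))
        header = "# region\tmean_dN\tmean_dS\tdN_dS_ratio_of_means\tregime"
        (out / "dnds.tsv").write_text("\n".join([header] + dnds_rows) + "\n")

    # --- stage: trees -----------------------------------------------------
    log.info("stage trees")
    if config.bootstrap_reps > 0:
        tree, _ = trees.bootstrap_support(rep_aln, n_reps=config.bootstrap_reps,
                                          seed=config.seed)
    else:
        tree = trees.nj_tree(idm)
    trees.write_newick(tree, out / "repeats_nj.nwk")

    lines = [f"{k}: {v}" for k, v in summary.items()]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    log.info("report bundle written to %s", out)
    return summary
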