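"""Stage orchestration over a run directory.

Each stage reads the previous stage's files from the run directory and writes
its own, so any stage can be rerun in isolation and the whole chain is
reproducible from the config and seed alone.  Stage order::

    simulate -> collapse -> classify -> annotate -> families -> profile

Missing upstream artifacts raise :class:`StageError` naming the stage to run
first.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import annotate as ann_mod
from . import families as fam_mod
from . import ingest, profiles, simdata
from .genomemap import MITO, NUCLEAR, Genome, classify, hits_from_str, hits_to_str


class StageError(RuntimeError):
    pass


@dataclass
class RunParams:
    """Analysis knobs shared by the stages (mapping allowances, the CPM
    retention threshold, and family construction settings)."""

    k_genome: int = 1
    k_pirna: int = 1
    k_mirna: int = 2
    cpm_threshold: float = 10.0
    anchor_min: int = 20
    require_shared_locus: bool = True

    def __post_init__(self):
        if self.cpm_threshold < 0:
            raise ValueError("cpm_threshold must be >= 0")
        for k in ("k_genome", "k_pirna", "k_mirna"):
            if not 0 <= getattr(self, k) <= 3:
                raise ValueError(f"{k} must be in 0..3")


def _require(outdir: Path, name: str, producer: str) -> Path:
    p = outdir / name
    if not p.exists():
        raise StageError(f"missing artifact '{name}': run the '{producer}' stage first")
    return p


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: simdata.SimConfig, outdir: Path) -> dict[str, Path]:
    res = simdata.simulate(cfg, outdir)
    out = {
        "mito.fasta": outdir / "mito.fasta",
        "nuclear.fasta": outdir / "nuclear.fasta",
        "mito_features.gff3": outdir / "mito_features.gff3",
        "pirna_db.fasta": outdir / "pirna_db.fasta",
        "mirna_db.fasta": outdir / "mirna_db.fasta",
        "truth.tsv": outdir / "truth.tsv",
        "samples.tsv": outdir / "samples.tsv",
    }
    out.update({f"reads/{p.name}": p for p in res.fastq_paths.values()})
    return out


def stage_collapse(outdir: Path, params: RunParams) -> dict[str, Path]:
    samples = pd.read_csv(_require(outdir, "samples.tsv", "simulate"), sep="\t")
    reads = {
        r.sample_id: _require(outdir, f"reads/{r.sample_id}.fastq", "simulate")
        for r in samples.itertuples()
    }
    counts, stats = ingest.collapse(reads)
    totals = ingest.library_totals(counts)
    cpm = ingest.compute_cpm(counts, totals)
    retained, flags = ingest.filter_cpm(counts, params.cpm_threshold, totals)
    for sid, st in stats.items():
        st.sequences_post_filter = int(flags[sid].sum())
    ingest.write_counts(counts, outdir / "counts.tsv")
    ingest.write_counts(retained, outdir / "retained_counts.tsv")
    cpm.loc[retained.index].to_csv(outdir / "retained_cpm.tsv", sep="\t")
    flags.astype(int).to_csv(outdir / "retained_flags.tsv", sep="\t")
    totals.rename("library_total").to_csv(outdir / "library_totals.tsv", sep="\t")
    ingest.stats_table(stats).to_csv(outdir / "library_stats.tsv", sep="\t")
    return {n: outdir / n for n in (
        "counts.tsv", "retained_counts.tsv", "retained_cpm.tsv",
        "retained_flags.tsv", "library_totals.tsv", "library_stats.tsv")}


def _load_genomes(outdir: Path) -> tuple[Genome, Genome]:
    nuclear = Genome.from_fasta(_require(outdir, "nuclear.fasta", "simulate"), name=NUCLEAR)
    mito = Genome.from_fasta(_require(outdir, "mito.fasta", "simulate"), circular=True, name=MITO)
    return nuclear, mito


def stage_classify(outdir: Path, params: RunParams) -> dict[str, Path]:
    retained = ingest.read_counts(_require(outdir, "retained_counts.tsv", "collapse"))
    nuclear, mito = _load_genomes(outdir)
    rows = []
    for seq in retained.index:
        label, hits = classify(seq, nuclear, mito, params.k_genome)
        rows.append({"sequence": seq, "genome_class": label, "hits": hits_to_str(hits)})
    pd.DataFrame(rows).to_csv(outdir / "classes.tsv", sep="\t", index=False)
    return {"classes.tsv": outdir / "classes.tsv"}


def stage_annotate(outdir: Path, params: RunParams) -> dict[str, Path]:
    classes = pd.read_csv(_require(outdir, "classes.tsv", "classify"), sep="\t", keep_default_na=False)
    pirna_db = ann_mod.load_reference(_require(outdir, "pirna_db.fasta", "simulate"))
    mirna_db = ann_mod.load_reference(_require(outdir, "mirna_db.fasta", "simulate"))
    features = ann_mod.load_features(_require(outdir, "mito_features.gff3", "simulate"))
    _, mito = _load_genomes(outdir)
    mito_len = mito.length(simdata.MITO_CONTIG)
    rows = []
    for r in classes.itertuples():
        seq = r.sequence
        dbm = ann_mod.categorize(seq, pirna_db, mirna_db, params.k_pirna, params.k_mirna)
        hits = hits_from_str(r.hits)
        mito_hits = [h for h in hits if h.genome == MITO]
        per_hit = [
            ann_mod.overlaps_to_str(ann_mod.assign_features(h, len(seq), features, mito_len))
            for h in mito_hits
        ]
        rows.append({
            "sequence": seq, "length": len(seq), "genome_class": r.genome_class,
            "category": dbm.category, "pirna_ids": ",".join(dbm.pirna_ids),
            "pirna_multi": int(dbm.pirna_multi), "mirna_ids": ",".join(dbm.mirna_ids),
            "hits": r.hits, "mito_overlaps": "&".join(per_hit),
        })
    pd.DataFrame(rows).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    return {"annotations.tsv": outdir / "annotations.tsv"}


def _load_annotations(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(
        _require(outdir, "annotations.tsv", "annotate"), sep="\t", keep_default_na=False
    )


def _members_from_annotations(ann: pd.DataFrame) -> list[fam_mod.FamilyMember]:
    return [
        fam_mod.FamilyMember(
            sequence=r.sequence,
            genome_class=r.genome_class,
            pirna_ids=[x for x in str(r.pirna_ids).split(",") if x],
            hits=hits_from_str(r.hits),
        )
        for r in ann.itertuples()
    ]


def stage_families(outdir: Path, params: RunParams) -> dict[str, Path]:
    ann = _load_annotations(outdir)
    retained = ingest.read_counts(_require(outdir, "retained_counts.tsv", "collapse"))
    _, mito = _load_genomes(outdir)
    members = _members_from_annotations(ann)
    fams = fam_mod.build_families(
        members,
        anchor_min=params.anchor_min,
        require_shared_locus=params.require_shared_locus,
        mito_length=mito.length(simdata.MITO_CONTIG),
    )
    for f in fams:
        fam_mod.assign_roles(f)
        fam_mod.infer_direction(f)
    fam_mod.families_table(fams, retained).to_csv(outdir / "families.tsv", sep="\t", index=False)
    summary = fam_mod.direction_proportions(fams)
    (outdir / "direction_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    fam_members = [m for f in fams for m in f.members]
    read_totals = retained.sum(axis=1).to_dict()
    fam_mod.length_by_class(fam_members, read_totals).to_csv(
        outdir / "length_by_class.tsv", sep="\t", index=False
    )
    return {n: outdir / n for n in ("families.tsv", "direction_summary.json", "length_by_class.tsv")}


def stage_profile(outdir: Path, params: RunParams) -> dict[str, Path]:
    ann = _load_annotations(outdir)
    retained = ingest.read_counts(_require(outdir, "retained_counts.tsv", "collapse"))
    cpm = pd.read_csv(_require(outdir, "retained_cpm.tsv", "collapse"), sep="\t", index_col="sequence")
    flags = pd.read_csv(
        _require(outdir, "retained_flags.tsv", "collapse"), sep="\t", index_col="sequence"
    ).astype(bool)
    features = ann_mod.load_features(_require(outdir, "mito_features.gff3", "simulate"))

    category = dict(zip(ann["sequence"], ann["category"]))
    gclass = dict(zip(ann["sequence"], ann["genome_class"]))
    lengths = dict(zip(ann["sequence"], ann["length"]))
    overlaps_by_seq = {
        r.sequence: [ann_mod.overlaps_from_str(part) for part in str(r.mito_overlaps).split("&") if part]
        for r in ann.itertuples()
        if r.mito_overlaps
    }

    table, props = profiles.summarize_counts(category, gclass, retained, flags)
    table.to_csv(outdir / "sample_table.tsv", sep="\t")

    mito_pirna = ann[
        ann["genome_class"].isin(profiles.MITO_CLASSES)
        & ann["category"].isin([ann_mod.CAT_PIRNA, ann_mod.CAT_DUAL])
    ]["sequence"].tolist()
    if not mito_pirna:
        raise ValueError("no mitochondrial piRNA sequences to profile")
    reads_w = retained.sum(axis=1)
    bias_seq, pos1_seq = profiles.positional_bias(mito_pirna)
    bias_read, pos1_read = profiles.positional_bias(
        mito_pirna, [float(reads_w.get(s, 0.0)) for s in mito_pirna]
    )
    bias_seq.to_csv(outdir / "bias_sequences.tsv", sep="\t")
    bias_read.to_csv(outdir / "bias_reads.tsv", sep="\t")

    mito_seqs = {s for s, c in gclass.items() if c in profiles.MITO_CLASSES}
    ov_mito = {s: v for s, v in overlaps_by_seq.items() if s in mito_seqs}
    fdist = profiles.feature_distribution(ov_mito, lengths, gclass, reads_w.to_dict())
    fdist.to_csv(outdir / "feature_distribution.tsv", sep="\t", index=False)
    profiles.per_kb_enrichment(fdist, features).to_csv(outdir / "per_kb.tsv", sep="\t", index=False)
    smat = profiles.strand_matrix(ov_mito, lengths, cpm.loc[sorted(mito_seqs & set(cpm.index))])
    smat.to_csv(outdir / "strand_matrix.tsv", sep="\t")
    coords, evr = profiles.pca_samples(smat)
    coords.assign(explained_variance_ratio=list(evr) + [float("nan")] * (len(coords) - len(evr))).to_csv(
        outdir / "pca.tsv", sep="\t"
    )

    dirsum = {}
    dpath = outdir / "direction_summary.json"
    if dpath.exists():
        dirsum = json.loads(dpath.read_text())
    metrics = {
        "proportions": props,
        "pos1_modal_sequences": pos1_seq,
        "pos1_modal_reads": pos1_read,
        "pos1_A_freq_sequences": float(bias_seq.loc[1, "A"]),
        "pos1_A_freq_reads": float(bias_read.loc[1, "A"]),
        "direction_summary": dirsum,
        "pca_explained_variance": [float(x) for x in evr],
    }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2) + "\n")
    return {n: outdir / n for n in (
        "sample_table.tsv", "bias_sequences.tsv", "bias_reads.tsv",
        "feature_distribution.tsv", "per_kb.tsv", "strand_matrix.tsv",
        "pca.tsv", "metrics.json")}


STAGES = ("simulate", "collapse", "classify", "annotate", "families", "profile")


@dataclass
class PipelineResult:
    sim: simdata.SimResult
    outputs: dict


def run_all(cfg: simdata.SimConfig, outdir: str | Path, params: RunParams | None = None) -> PipelineResult:
    """Run the full chain into ``outdir``; returns the simulation objects and
    the per-stage output paths."""
    params = params or RunParams()
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    sim = simdata.simulate(cfg, outdir)
    outputs = {"simulate": {"truth.tsv": outdir / "truth.tsv"}}
    outputs["collapse"] = stage_collapse(outdir, params)
    outputs["classify"] = stage_classify(outdir, params)
    outputs["annotate"] = stage_annotate(outdir, params)
    outputs["families"] = stage_families(outdir, params)
    outputs["profile"] = stage_profile(outdir, params)
    return PipelineResult(sim, outputs)


def manifest_entry(params) -> dict:
    return dataclasses.asdict(params) if dataclasses.is_dataclass(params) else dict(params)
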