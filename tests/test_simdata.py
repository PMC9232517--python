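"""The synthetic cohort generator: determinism, genome/feature layout, NUMT
planting, family realizability (checked against brute-force substring scans),
and read emission contracts."""
import numpy as np
import pandas as pd
import pytest

from mitopirna import simdata
from mitopirna._util import revcomp, substreams

TINY = dict(
    reads_per_sample=1500,
    nuclear_contigs=(("chr1", 15000), ("chr2", 15000)),
    n_mito_bg_loci=60,
    n_nuclear_bg_loci=120,
    n_noise=30,
    n_nu_pirnas=10,
    n_nu_mirnas=5,
    decoy_db_entries=10,
)


def _scan(seq: str, texts: list[str]) -> bool:
    rc = revcomp(seq)
    return any(t.find(seq) != -1 or t.find(rc) != -1 for t in texts)


def test_identical_config_gives_byte_identical_outputs(tmp_path):
    cfg = simdata.SimConfig(seed=3, **TINY)
    a = simdata.simulate(cfg, tmp_path / "a")
    b = simdata.simulate(simdata.SimConfig(seed=3, **TINY), tmp_path / "b")
    files_a = sorted(p.relative_to(a.outdir) for p in (tmp_path / "a").rglob("*") if p.is_file())
    files_b = sorted(p.relative_to(b.outdir) for p in (tmp_path / "b").rglob("*") if p.is_file())
    assert files_a == files_b
    for rel in files_a:
        assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes(), rel


def test_mito_genome_layout(small_run):
    cfg, feats = small_run.sim.cfg, small_run.sim.mito_features
    dloop = feats[feats["type"] == "D-loop"]
    assert len(dloop) == 1 and int(dloop["end"].iloc[0]) == cfg.mito_length
    assert (feats["type"] == "tRNA").sum() == cfg.n_trna
    assert (feats["type"] == "rRNA").sum() == len(cfg.rrna_lengths)
    assert feats["start"].min() >= 1 and feats["end"].max() <= cfg.mito_length
    ordered = feats.sort_values("start")
    assert (ordered["start"].values[1:] > ordered["end"].values[:-1]).all()  # non-overlap
    covered = (feats["end"] - feats["start"] + 1).sum()
    assert covered < cfg.mito_length
    assert set(feats["strand"]) >= {"+", "-"}  # tRNAs on both strands


def test_feature_sizing_error():
    cfg = simdata.SimConfig(seed=0, mito_length=3000, **TINY)
    rng = substreams(0, ["m"])["m"]
    with pytest.raises(ValueError, match="without overlap"):
        simdata.gen_mito_genome(cfg, rng)


def test_numt_table_and_zero_divergence_verbatim(small_run):
    sim = small_run.sim
    assert len(sim.numt_table) == sim.cfg.n_numts
    for r in sim.numt_table.itertuples():
        frag = sim.mito[r.mito_start - 1 : r.mito_end]
        if r.strand == "-":
            frag = revcomp(frag)
        assert r.n_substitutions == 0
        assert sim.contigs[r.contig][r.contig_start - 1 : r.contig_end] == frag


def test_numt_sizing_error():
    cfg = simdata.SimConfig(seed=0, numt_length_range=(16000, 16200), **TINY)
    rngs = substreams(0, ["m", "n"])
    mito, feats = simdata.gen_mito_genome(cfg, rngs["m"])
    with pytest.raises(ValueError, match="does not fit"):
        simdata.gen_nuclear_genome(cfg, mito, feats, rngs["n"])


def test_reference_set_composition(small_run):
    plan = small_run.sim.plan
    db_seqs = set(plan.pirna_db.values())
    for fam in plan.families:
        matures = fam.matures
        assert len(matures) == len(small_run.sim.cfg.family_ladder) - 1
        assert all(m in db_seqs for m in matures)
        assert fam.precursor not in db_seqs
    dual = set(plan.pirna_db.values()) & set(plan.mirna_db.values())
    assert len(dual) == 1  # exactly one planted dual miRNA/piRNA sequence


def test_planted_directions_agree_with_substring_scan_oracle(small_run):
    sim = small_run.sim
    mito_texts = [sim.mito + sim.mito[:74]]
    nuc_texts = list(sim.contigs.values())
    for fam in sim.plan.families:
        prec_mt, prec_nu = _scan(fam.precursor, mito_texts), _scan(fam.precursor, nuc_texts)
        mats_mt = all(_scan(m, mito_texts) for m in fam.matures)
        mats_nu = all(_scan(m, nuc_texts) for m in fam.matures)
        if fam.direction == "retrograde":
            assert prec_mt and not prec_nu and mats_mt and mats_nu
        elif fam.direction == "anterograde":
            assert prec_nu and not prec_mt and mats_mt and mats_nu
        else:  # self: confined to the mitochondrial genome
            assert prec_mt and not prec_nu and mats_mt and not mats_nu


def test_decoys_and_noise_are_unmappable(small_run):
    sim = small_run.sim
    texts = [sim.mito + sim.mito[:74]] + list(sim.contigs.values())
    decoys = [s for name, s in sim.plan.pirna_db.items() if "decoy" in name]
    assert decoys and not any(_scan(s, texts) for s in decoys)
    noise = sim.truth[sim.truth["group"] == "noise"]
    assert (noise["true_class"] == "UNMAPPED").all()


def test_per_sample_read_conservation(small_run):
    sim = small_run.sim
    emitted = sim.counts.sum(axis=0)
    for s in sim.cfg.samples:
        assert emitted[s.sample_id] == s.total_reads


def test_forced_first_position_bias(tmp_path):
    cfg = simdata.SimConfig(seed=5, pos1_A_bias=1.0, **TINY)
    sim = simdata.simulate(cfg, tmp_path)
    bg = sim.truth[sim.truth["group"].isin(["mito_bg", "nuclear_bg"])]
    assert len(bg) > 0
    assert bg["sequence"].str.startswith("A").all()


def test_forced_dloop_reverse_orientation(small_run):
    # default dloop_reverse_fraction is 1.0: every read touching the D-loop is antisense
    truth = small_run.sim.truth
    dloop = truth[truth["true_features"].str.contains("D-loop", na=False)]
    assert len(dloop) > 0
    assert (dloop["sense"] == "-").all()


def test_truth_covers_every_emitted_sequence_once(small_run):
    sim = small_run.sim
    emitted = set(sim.counts.index[sim.counts.sum(axis=1) > 0])
    assert set(sim.truth["sequence"]) == emitted
    assert sim.truth["sequence"].is_unique
    assert sim.truth["sequence"].str.len().max() <= 75


def test_family_member_expression_recovers_generating_mean(small_run):
    # planted member counts follow the multinomial around pool probabilities:
    # observed totals within 3 SD of the expectation for every family member
    sim = small_run.sim
    pool = sim.pool.set_index("sequence")
    fam = pool[pool["family_id"] != ""]
    n = sum(s.total_reads for s in sim.cfg.samples)
    for seq, row in fam.iterrows():
        expected = row["prob"] * n
        sd = np.sqrt(n * row["prob"] * (1 - row["prob"]))
        assert abs(sim.counts.loc[seq].sum() - expected) <= 3 * sd + 1


def test_config_validation_and_round_trip(tmp_path):
    with pytest.raises(ValueError, match="strictly decreasing"):
        simdata.SimConfig(family_ladder=(30, 30, 25))
    with pytest.raises(ValueError, match="pos1_A_bias"):
        simdata.SimConfig(pos1_A_bias=1.5)
    with pytest.raises(ValueError, match="unique"):
        simdata.SimConfig(samples=[
            simdata.SampleMeta("x", "PGC", "F", "11.5", 10),
            simdata.SampleMeta("x", "SC", "M", "12.5", 10),
        ])
    cfg = simdata.SimConfig(seed=9, **TINY)
    cfg.to_yaml(tmp_path / "c.yaml")
    assert simdata.SimConfig.from_yaml(tmp_path / "c.yaml") == cfg
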