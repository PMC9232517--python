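"""5'-anchored family construction, role assignment, eligibility and
communication-direction inference."""
import numpy as np
import pytest

from mitopirna import families as fam
from mitopirna.genomemap import MITO, NUCLEAR, GenomeHit

BASE = "ATGCTGACGGATTCAGCTTAGCGATCCGATAGCTTACGGATCCATGCAATTGGCCTTAAG"  # 60 nt


def member(seq, cls="MT", pirna=(), start=101, strand="+", genome=MITO, contig="chrM"):
    if strand == "+":
        hit = GenomeHit(genome, contig, "+", start, 0)
    else:
        # leftmost-start convention: a 5' prefix of a minus-strand sequence sits
        # at the right end of the representative's window
        hit = GenomeHit(genome, contig, "-", start + 60 - len(seq), 0)
    return fam.FamilyMember(seq, cls, pirna_ids=list(pirna), hits=[hit])


def ladder(lengths=(60, 30, 28, 25), **kw):
    return [member(BASE[:L], **kw) for L in lengths]


def test_planted_ladder_forms_one_family_with_longest_representative():
    fams = fam.build_families(ladder(), mito_length=16299)
    assert len(fams) == 1
    f = fams[0]
    assert len(f.members) == 4
    assert f.representative == BASE


def test_minus_strand_ladder_shares_anchor():
    fams = fam.build_families(ladder(strand="-"), mito_length=16299)
    assert len(fams) == 1 and len(fams[0].members) == 4


def test_short_shared_prefix_makes_no_family():
    a = member(BASE[:19] + "A" * 11)  # shares only 19 nt with BASE
    b = member(BASE[:30])
    assert fam.build_families([a, b], mito_length=16299) == []


def test_singletons_are_dropped():
    assert fam.build_families([member(BASE)], mito_length=16299) == []


def test_locus_requirement_separates_prefix_twins():
    a, b = member(BASE), member(BASE[:30], start=900)
    assert fam.build_families([a, b], mito_length=16299) == []
    joined = fam.build_families([a, b], require_shared_locus=False, mito_length=16299)
    assert len(joined) == 1


def test_family_partition_is_disjoint():
    members = ladder() + [member(("T" + BASE[1:])[:L], start=400) for L in (55, 26)]
    fams = fam.build_families(members, mito_length=16299)
    seqs = [m.sequence for f in fams for m in f.members]
    assert len(seqs) == len(set(seqs))


def test_prefix_chain_invariant():
    fams = fam.build_families(ladder(), mito_length=16299)
    chain = sorted((m.sequence for m in fams[0].members), key=len)
    assert all(b.startswith(a) for a, b in zip(chain, chain[1:]))


def test_role_assignment_and_eligibility():
    f = fam.build_families(
        [
            member(BASE, cls="MT"),
            member(BASE[:30], cls="NUMT", pirna=["p1"]),
            member(BASE[:28], cls="NUMT", pirna=["p2"]),
            member(BASE[:25], cls="NUMT", pirna=["p3"]),
        ],
        mito_length=16299,
    )[0]
    fam.assign_roles(f)
    roles = {m.sequence: m.role for m in f.members}
    assert roles[BASE] == "precursor"
    assert all(roles[BASE[:L]] == "mature" for L in (30, 28, 25))
    assert f.eligible


def test_unmatched_member_shorter_than_a_mature_is_not_precursor():
    f = fam.build_families(
        [
            member(BASE, cls="MT"),
            member(BASE[:50], cls="MT", pirna=["p1"]),  # 50-mer mature
            member(BASE[:45], cls="MT"),  # unmatched, shorter than the mature
        ],
        mito_length=16299,
    )[0]
    fam.assign_roles(f)
    roles = {m.length: m.role for m in f.members}
    assert roles[60] == "precursor" and roles[50] == "mature" and roles[45] == "none"


def test_unmapped_long_member_is_not_precursor():
    m = member(BASE, cls="UNMAPPED")
    m.hits = []
    f = fam.build_families(
        [m, member(BASE[:30], cls="MT", pirna=["p1"]), member(BASE[:25], cls="MT", pirna=["p2"])],
        require_shared_locus=False,
        mito_length=16299,
    )[0]
    fam.assign_roles(f)
    assert {x.role for x in f.members if x.sequence == BASE} == {"none"}
    assert not f.eligible  # no precursor left


@pytest.mark.parametrize(
    "pre,mats,expected",
    [
        (["MT"], ["NUMT", "NUMT", "MT"], "retrograde"),
        (["MT"], ["NUMT", "MT"], "retrograde"),
        (["NU"], ["NUMT", "NUMT"], "anterograde"),
        (["NU"], ["MT", "MT"], "anterograde"),
        (["MT"], ["MT", "MT"], "self"),
        (["NU"], ["NU", "NU"], "unresolved"),  # no MT/NUMT member -> ineligible
        (["NUMT"], ["NUMT", "NUMT"], "unresolved"),  # precursor not exclusive to one genome
    ],
)
def test_direction_rules(pre, mats, expected):
    members = [member(BASE, cls=c) for c in pre] + [
        member(BASE[: 30 - i], cls=c, pirna=[f"p{i}"]) for i, c in enumerate(mats)
    ]
    f = fam.PiRNAFamily("F1", members)
    fam.assign_roles(f)
    assert fam.infer_direction(f) == expected


def test_direction_is_order_invariant():
    members = [member(BASE, cls="MT")] + [
        member(BASE[:L], cls="NUMT", pirna=["p"]) for L in (30, 28)
    ]
    rng = np.random.default_rng(0)
    labels = set()
    for _ in range(5):
        perm = [members[i] for i in rng.permutation(len(members))]
        f = fam.PiRNAFamily("F", list(perm))
        fam.assign_roles(f)
        labels.add(fam.infer_direction(f))
    assert labels == {"retrograde"}


def test_direction_proportions_arithmetic():
    fams = []
    for i, d in enumerate(["retrograde"] * 8 + ["anterograde"] * 2):
        f = fam.PiRNAFamily(f"F{i}", ladder())
        f.eligible, f.direction = True, d
        fams.append(f)
    summary = fam.direction_proportions(fams)
    assert summary["percentages"] == {"retrograde": 80.0, "anterograde": 20.0, "self": 0.0}
    assert abs(sum(summary["percentages"].values()) - 100.0) < 0.1
    assert not summary["empty"]


def test_direction_proportions_empty_flag():
    assert fam.direction_proportions([])["empty"]


def test_length_by_class_concentrates_mass_where_planted():
    members = [
        member(BASE, cls="MT"),
        member(BASE[:30], cls="NUMT", pirna=["p1"]),
        member(BASE[:25], cls="NUMT", pirna=["p2"]),
    ]
    f = fam.PiRNAFamily("F1", members)
    fam.assign_roles(f)
    totals = {BASE: 50, BASE[:30]: 400, BASE[:25]: 150}
    tab = fam.length_by_class(members, totals)
    assert tab.loc[tab["length"] == 60, "genome_class"].tolist() == ["MT"]
    assert tab["reads"].sum() == 600
    numt = tab[tab["genome_class"] == "NUMT"]
    assert set(numt["length"]) == {30, 25}
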