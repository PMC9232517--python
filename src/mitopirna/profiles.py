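"""Summary surfaces: per-sample count table, positional nucleotide bias,
mitochondrial feature distributions, strand-resolved expression matrices, and
sample PCA.

Expression attribution: a sequence with several minimal-stratum mitochondrial
placements has its counts divided equally among them, and within one placement
proportionally to the overlap length with each feature (intergenic remainder
included), so feature totals conserve the mitochondrial read/CPM totals.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .annotate import CAT_DUAL, CAT_MIRNA, CAT_PIRNA, FeatureOverlap
from .genomemap import CLASS_MT, CLASS_NU, CLASS_NUMT

#: canonical piRNA length upper bound; positions beyond it are not profiled
BIAS_LMAX = 35

MITO_CLASSES = (CLASS_MT, CLASS_NUMT)


# ---------------------------------------------------------------------------
# per-sample summary table

def summarize_counts(
    category: Mapping[str, str],
    genome_class: Mapping[str, str],
    counts: pd.DataFrame,
    retained_in: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Per-sample summary of sequences and reads by category and genome class.

    A sequence contributes to sample ``s`` only where its retention flag is set
    (CPM >= threshold in that sample).  Dual miRNA/piRNA sequences count in the
    piRNA columns.  Returns the per-sample table (plus an ``Average`` row) and
    the cohort-level derived proportions.
    """
    seqs = counts.index
    cat = pd.Series({s: category[s] for s in seqs})
    cls = pd.Series({s: genome_class[s] for s in seqs})
    is_mito = cls.isin(MITO_CLASSES)
    is_pirna = cat.isin([CAT_PIRNA, CAT_DUAL])
    is_mirna = cat == CAT_MIRNA

    cells = {
        "mito": is_mito,
        "mirna_NU": is_mirna & (cls == CLASS_NU),
        "mirna_NUMT": is_mirna & (cls == CLASS_NUMT),
        "mirna_MT": is_mirna & (cls == CLASS_MT),
        "pirna_NU": is_pirna & (cls == CLASS_NU),
        "pirna_NUMT": is_pirna & (cls == CLASS_NUMT),
        "pirna_MT": is_pirna & (cls == CLASS_MT),
    }
    rows = []
    for s in counts.columns:
        flag = retained_in[s]
        cnt = counts[s].where(flag, 0)
        row = {"sample_id": s, "total_seq": int(flag.sum()), "total_reads": int(cnt.sum())}
        for name, mask in cells.items():
            sel = mask.values & flag.values
            row[f"{name}_seq"] = int(sel.sum())
            row[f"{name}_reads"] = int(cnt.values[sel].sum())
        rows.append(row)
    table = pd.DataFrame(rows).set_index("sample_id")
    avg = table.mean(axis=0)
    table.loc["Average"] = avg

    mito_reads = avg["mito_reads"]
    props = {
        "prop_mito_of_total_reads_pct": 100.0 * mito_reads / avg["total_reads"] if avg["total_reads"] else 0.0,
        "prop_mirna_of_mito_reads_pct": (
            100.0 * (avg["mirna_NUMT_reads"] + avg["mirna_MT_reads"]) / mito_reads if mito_reads else 0.0
        ),
        "prop_pirna_of_mito_reads_pct": (
            100.0 * (avg["pirna_NUMT_reads"] + avg["pirna_MT_reads"]) / mito_reads if mito_reads else 0.0
        ),
        "prop_pirna_numt_of_mito_reads_pct": 100.0 * avg["pirna_NUMT_reads"] / mito_reads if mito_reads else 0.0,
        "prop_pirna_mt_of_mito_reads_pct": 100.0 * avg["pirna_MT_reads"] / mito_reads if mito_reads else 0.0,
    }
    return table, props


# ---------------------------------------------------------------------------
# positional nucleotide bias

def positional_bias(
    sequences: Sequence[str],
    weights: Sequence[float] | None = None,
    lmax: int = BIAS_LMAX,
) -> tuple[pd.DataFrame, str]:
    """Position x nucleotide frequency matrix over positions 1..lmax.

    ``weights=None`` gives the sequence-weighted variant (each unique sequence
    counts once); passing read counts gives the read-weighted variant.  Each
    row is normalized over the sequences long enough to cover that position.
    Returns the matrix and the modal nucleotide at position 1.
    """
    if len(sequences) == 0:
        raise ValueError("positional bias of an empty sequence set")
    if weights is None:
        weights = np.ones(len(sequences))
    w = np.asarray(weights, dtype=float)
    mat = np.zeros((lmax, 4))
    idx = {b: i for i, b in enumerate("ACGT")}
    for seq, wt in zip(sequences, w):
        for pos, base in enumerate(seq[:lmax]):
            mat[pos, idx[base]] += wt
    totals = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freq = np.where(totals > 0, mat / totals, 0.0)
    df = pd.DataFrame(freq, index=pd.RangeIndex(1, lmax + 1, name="position"), columns=list("ACGT"))
    pos1_modal = df.iloc[0].idxmax()
    return df, pos1_modal


# ---------------------------------------------------------------------------
# feature distribution and strand matrix

def _attribution(
    overlaps_by_seq: Mapping[str, list[list[FeatureOverlap]]],
    length_by_seq: Mapping[str, int],
):
    """Yield (sequence, overlap, weight) with weight = 1/n_hits * overlap/len."""
    for seq, per_hit in overlaps_by_seq.items():
        if not per_hit:
            continue
        L = length_by_seq[seq]
        split = 1.0 / len(per_hit)
        for overlaps in per_hit:
            for ov in overlaps:
                yield seq, ov, split * ov.overlap_nt / L


def feature_distribution(
    overlaps_by_seq: Mapping[str, list[list[FeatureOverlap]]],
    length_by_seq: Mapping[str, int],
    genome_class: Mapping[str, str],
    read_totals: Mapping[str, float],
) -> pd.DataFrame:
    """Per-feature-type totals of sequences and reads, MT and NUMT separately.

    Sequence totals use the same fractional attribution as reads, so both
    conserve their mitochondrial totals.
    """
    acc: dict[tuple[str, str], dict[str, float]] = {}
    for seq, ov, w in _attribution(overlaps_by_seq, length_by_seq):
        key = (ov.feature_type, genome_class[seq])
        cell = acc.setdefault(key, {"sequences": 0.0, "reads": 0.0})
        cell["sequences"] += w
        cell["reads"] += w * float(read_totals.get(seq, 0.0))
    rows = [
        {"feature_type": ft, "genome_class": gc, **vals}
        for (ft, gc), vals in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=["feature_type", "genome_class", "sequences", "reads"])


def strand_matrix(
    overlaps_by_seq: Mapping[str, list[list[FeatureOverlap]]],
    length_by_seq: Mapping[str, int],
    cpm: pd.DataFrame,
) -> pd.DataFrame:
    """(feature, orientation) x sample CPM matrix for heatmap-style display.

    Row labels are "<feature>:Fwd" / "<feature>:Rvr"; column sums equal each
    sample's total CPM over the sequences provided.
    """
    rows: dict[str, np.ndarray] = {}
    ncol = cpm.shape[1]
    for seq, ov, w in _attribution(overlaps_by_seq, length_by_seq):
        label = f"{ov.feature_name}:{'Fwd' if ov.orientation == 'forward' else 'Rvr'}"
        vec = rows.setdefault(label, np.zeros(ncol))
        if seq in cpm.index:
            vec += w * cpm.loc[seq].to_numpy(dtype=float)
    df = pd.DataFrame(rows, index=cpm.columns).T.sort_index()
    df.index.name = "feature_orientation"
    return df


def per_kb_enrichment(fdist: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Reads per feature type per annotated kilobase."""
    kb = (
        features.assign(kb=lambda d: (d["end"] - d["start"] + 1) / 1000.0)
        .groupby("type")["kb"]
        .sum()
    )
    reads = fdist.groupby("feature_type")["reads"].sum()
    out = pd.DataFrame({"reads": reads, "annotated_kb": kb}).dropna()
    out["reads_per_kb"] = out["reads"] / out["annotated_kb"]
    return out.reset_index(names="feature_type")


# ---------------------------------------------------------------------------
# sample PCA

def pca_samples(
    matrix: pd.DataFrame,
    n_components: int = 2,
    min_nonzero_fraction: float = 0.5,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples from a (row-feature x sample) expression matrix.

    Rows expressed in fewer than ``min_nonzero_fraction`` of the samples are
    dropped first (a sporadic single-read row contributes a large, purely
    stochastic log-scale spike).  The remaining matrix is log2(CPM+1)
    transformed and row-centered; samples are the observations.  Component
    signs are fixed by making each component's largest-magnitude loading
    positive, so results are deterministic.  Returns per-sample coordinates
    and the explained-variance fractions.
    """
    if matrix.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    if n_components > matrix.shape[1]:
        raise ValueError("more components than samples requested")
    expressed = (matrix > 0).mean(axis=1) >= min_nonzero_fraction
    if expressed.any():
        matrix = matrix.loc[expressed]
    X = np.log2(matrix.to_numpy(dtype=float) + 1.0)
    X = X - X.mean(axis=1, keepdims=True)
    if np.allclose(X, 0):
        coords = pd.DataFrame(
            np.zeros((matrix.shape[1], n_components)),
            index=matrix.columns,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        )
        return coords, np.zeros(n_components)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X.T)
    comps = pca.components_
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] *= -1
            scores[:, i] *= -1
    coords = pd.DataFrame(
        scores, index=matrix.columns, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    return coords, pca.explained_variance_ratio_
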