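"""Cross-cohort signature comparison and genomic-context annotation.

Signatures from different cohorts are compared by the percentage of
top-ranked differentially methylated positions (DMPs) they share, by
their overall mean methylation shift, and by average-linkage clustering
of their effect vectors.  Individual probes are placed relative to CpG
islands (island / shore / shelf / inter-CGI, with 2 kb and 4 kb flanks)
and gene model parts (promoter, UTRs, CDS, intron).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import pdist

from .errors import FormatError, ValidationError

SHORE_BP = 2000
SHELF_BP = 4000
CGI_CLASSES = ("island", "shore", "shelf", "inter_cgi")
GENE_PART_PRIORITY = ("promoter", "five_utr", "cds", "three_utr", "intron", "intergenic")


@dataclass
class SignatureSet:
    """Per-cohort DMP lists (ordered by significance) with signed effects."""

    dmp_ids: dict[str, list[str]]
    delta_beta: dict[str, pd.Series]

    def cohorts(self) -> list[str]:
        return list(self.dmp_ids)


def dmp_overlap(sigs: SignatureSet, top_n: int = 500) -> pd.DataFrame:
    """Pairwise percentage of shared top-N DMPs.

    Entry (A, B) is ``100 * |top_n(A) & top_n(B)| / |top_n(A)|`` — the
    denominator is the row cohort's set, so the matrix is asymmetric when
    a cohort has fewer than ``top_n`` DMPs (all available are used, with
    a warning).  The diagonal is exactly 100.
    """
    names = sigs.cohorts()
    if len(names) < 2:
        raise ValidationError("need at least 2 cohorts for overlap")
    tops: dict[str, set[str]] = {}
    for name in names:
        ids = sigs.dmp_ids[name]
        if len(ids) < top_n:
            warnings.warn(f"cohort {name!r} has only {len(ids)} DMPs (< {top_n})")
        tops[name] = set(ids[:top_n])
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            mat.loc[a, b] = 100.0 * len(tops[a] & tops[b]) / len(tops[a])
        mat.loc[a, a] = 100.0
    return mat


def global_mean_difference(sigs: SignatureSet, cohort: str) -> float:
    """Signed mean of the cohort's per-DMP beta differences."""
    s = sigs.delta_beta[cohort]
    if s.empty:
        raise ValidationError(f"cohort {cohort!r} has no DMPs")
    return float(s.mean())


def cohort_tree(
    sigs: SignatureSet, top_n: int = 500
) -> tuple[np.ndarray, list[str], str]:
    """Average-linkage clustering of cohorts on zero-filled effect vectors.

    Each cohort is represented by its signed delta-beta vector over the
    union of all cohorts' top-N DMPs (absent probes contribute 0);
    distances are Euclidean.  Returns the linkage matrix, the cohort
    label order, and a Newick serialization with branch heights.
    """
    names = sigs.cohorts()
    if len(names) < 3:
        raise ValidationError("need at least 3 cohorts for a tree")
    union: list[str] = sorted(
        set().union(*(set(sigs.dmp_ids[n][:top_n]) for n in names))
    )
    vectors = np.zeros((len(names), len(union)))
    pos = {p: i for i, p in enumerate(union)}
    for i, n in enumerate(names):
        s = sigs.delta_beta[n]
        for p in sigs.dmp_ids[n][:top_n]:
            if p in s.index:
                vectors[i, pos[p]] = s[p]
    Z = _hier.linkage(pdist(vectors, metric="euclidean"), method="average")
    return Z, names, _linkage_to_newick(Z, names)


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = h
    return nodes[n + len(Z) - 1] + ";"


def annotate_cgi(probes: pd.DataFrame, cgi: pd.DataFrame) -> pd.Series:
    """Classify probes relative to CpG islands.

    ``probes`` needs columns probe_id/chrom/pos; ``cgi`` chrom/start/end
    (0-based half-open, non-overlapping per chromosome).  A probe inside
    an island is ``island``; within 2 kb of the nearest island boundary,
    ``shore``; within 2-4 kb, ``shelf``; else ``inter_cgi``.  The nearest
    island governs, ties going to the smaller-coordinate island; probes
    on chromosomes without islands are ``inter_cgi`` with a warning.
    """
    out = pd.Series(index=probes["probe_id"].to_numpy(), dtype=object)
    warned: set[str] = set()
    by_chrom = {c: g.sort_values("start") for c, g in cgi.groupby("chrom")}
    for chrom, grp in probes.groupby("chrom"):
        track = by_chrom.get(chrom)
        if track is None:
            if chrom not in warned:
                warnings.warn(f"no islands on {chrom!r}; probes set to inter_cgi")
                warned.add(chrom)
            out[grp["probe_id"].to_numpy()] = "inter_cgi"
            continue
        starts = track["start"].to_numpy(dtype=np.int64)
        ends = track["end"].to_numpy(dtype=np.int64)
        pos = grp["pos"].to_numpy(dtype=np.int64)
        # distance to each probe's nearest island (0 if inside)
        inside = np.zeros(len(pos), dtype=bool)
        dist = np.full(len(pos), np.iinfo(np.int64).max)
        for s, e in zip(starts, ends):
            d = np.where(pos < s, s - pos, np.where(pos >= e, pos - e, 0))
            inside |= d == 0
            dist = np.minimum(dist, d)
        cls = np.where(
            inside, "island",
            np.where(dist <= SHORE_BP, "shore",
                     np.where(dist <= SHELF_BP, "shelf", "inter_cgi")),
        )
        out[grp["probe_id"].to_numpy()] = cls
    return out


def annotate_gene_part(probes: pd.DataFrame, gene_model: pd.DataFrame) -> pd.DataFrame:
    """Overlap probes with gene-model part intervals.

    ``gene_model`` needs chrom/start/end/gene/transcript/part/strand rows
    (half-open intervals; promoters are 2 kb upstream of the transcription
    start, already strand-aware in the track).  Returns per probe the set
    of overlapping parts and a single priority label
    (promoter > five_utr > cds > three_utr > intron > intergenic).
    """
    if (gene_model["end"] <= gene_model["start"]).any():
        bad = gene_model.loc[gene_model["end"] <= gene_model["start"]]
        raise FormatError(f"malformed gene intervals (end <= start): {bad.index.tolist()[:5]}")
    part_sets: list[set[str]] = []
    labels: list[str] = []
    by_chrom = dict(tuple(gene_model.groupby("chrom")))
    for _, row in probes.iterrows():
        track = by_chrom.get(row["chrom"])
        parts: set[str] = set()
        if track is not None:
            hit = track[(track["start"] <= row["pos"]) & (row["pos"] < track["end"])]
            parts = set(hit["part"])
        part_sets.append(parts)
        label = "intergenic"
        for p in GENE_PART_PRIORITY:
            if p in parts:
                label = p
                break
        labels.append(label)
    return pd.DataFrame(
        {
            "probe_id": probes["probe_id"].to_numpy(),
            "gene_parts": part_sets,
            "gene_part": labels,
        }
    ).set_index("probe_id")


def context_composition(cgi_classes: pd.Series) -> pd.Series:
    """Percentage composition over the four CGI classes (sums to 100)."""
    counts = cgi_classes.value_counts()
    comp = pd.Series({c: 100.0 * counts.get(c, 0) / len(cgi_classes) for c in CGI_CLASSES})
    return comp
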