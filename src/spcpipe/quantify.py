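"""Maximum-parsimony protein inference and NSAF spectral-count quantification.

Parsimony chooses the smallest protein set that explains all observed
peptides (greedy minimal set cover); proteins whose peptides are all
explained by a chosen leader collapse into that leader's group. Spectral
counts (SpC) per group leader and sample are then normalised by NSAF:
NSAF_{i,s} = (SpC_{i,s}/L_i) / sum_j (SpC_{j,s}/L_j), so each sample column
lives on the simplex and lengths no longer confound abundances.
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .design import StudyDesign


@dataclass(frozen=True)
class ProteinGroup:
    """Parsimony unit: a leader accession, the member accessions it
    subsumes (each member's observed peptides are a subset of the
    leader's), and the leader's observed peptide set."""

    leader: str
    members: frozenset[str]
    peptides: frozenset[str]
    leader_length: int | None = None


def infer_parsimony_groups(
    peptide_to_proteins: Mapping[str, set[str]],
    lengths: Mapping[str, int] | None = None,
) -> list[ProteinGroup]:
    """Greedy minimal set cover of the observed peptides.

    Repeatedly selects the protein explaining the most still-uncovered
    peptides (ties: more total observed peptides, then lexicographically
    smaller accession) until every peptide is covered. Non-leader proteins
    whose peptide set is contained in a leader's become members of the
    first such leader (in selection order). The result depends only on the
    peptide->protein map, not on its iteration order.
    """
    if not peptide_to_proteins:
        raise ValueError("empty peptide map")
    prot_peps: dict[str, set[str]] = {}
    for pep, prots in peptide_to_proteins.items():
        for p in prots:
            prot_peps.setdefault(p, set()).add(pep)

    uncovered = set(peptide_to_proteins)
    heap = [(-len(peps), -len(peps), acc) for acc, peps in prot_peps.items()]
    heapq.heapify(heap)
    leaders: list[str] = []
    while uncovered:
        negc, negt, acc = heapq.heappop(heap)
        cur = len(prot_peps[acc] & uncovered)
        if cur == 0:
            continue
        if cur != -negc:  # stale entry: re-insert with the fresh count
            heapq.heappush(heap, (-cur, negt, acc))
            continue
        leaders.append(acc)
        uncovered -= prot_peps[acc]

    leader_peps = {a: prot_peps[a] for a in leaders}
    members: dict[str, set[str]] = {a: {a} for a in leaders}
    for acc, peps in prot_peps.items():
        if acc in leader_peps:
            continue
        for lead in leaders:
            if peps <= leader_peps[lead]:
                members[lead].add(acc)
                break
    return [
        ProteinGroup(
            leader=a,
            members=frozenset(members[a]),
            peptides=frozenset(leader_peps[a]),
            leader_length=None if lengths is None else int(lengths[a]),
        )
        for a in sorted(leaders)
    ]


def peptide_map_from_psms(psms: pd.DataFrame) -> dict[str, set[str]]:
    """Observed peptide -> union of mapped accessions over all PSMs."""
    out: dict[str, set[str]] = {}
    if psms["accessions"].str.contains(";").any():
        for pep, accs in zip(psms["peptide"], psms["accessions"]):
            out.setdefault(pep, set()).update(accs.split(";"))
    else:
        for pep, acc in zip(psms["peptide"], psms["accessions"]):
            out.setdefault(pep, set()).add(acc)
    return out


def assemble_count_matrix(
    final_psms: pd.DataFrame,
    groups: list[ProteinGroup],
    design: StudyDesign,
    sample_of_spectrum: Callable[[str], str] | Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Spectral counts per protein-group leader and sample.

    A PSM contributes one count to the group owning its peptide; peptides
    claimed by two or more distinct final groups are ambiguous and
    contribute nothing (their PSM count is returned separately, together
    with PSMs whose peptide belongs to no surviving group).
    """
    pep_owner: dict[str, str | None] = {}
    for g in groups:
        for pep in g.peptides:
            pep_owner[pep] = None if pep in pep_owner else g.leader

    if sample_of_spectrum is None:
        # default simulated spectrum ids encode the sample as "<sample>:<n>"
        samples = final_psms["spectrum_id"].str.rsplit(":", n=1).str[0]
    else:
        f = sample_of_spectrum.get if isinstance(sample_of_spectrum, Mapping) else sample_of_spectrum
        samples = final_psms["spectrum_id"].map(f)
    unknown = set(samples) - set(design.all_samples)
    if unknown:
        raise ValueError(f"spectrum maps to unknown sample id(s): {sorted(unknown)[:5]}")
    owners = final_psms["peptide"].map(pep_owner)
    excluded = int(owners.isna().sum())
    tab = (
        pd.DataFrame({"leader": owners, "sample": samples})
        .dropna(subset=["leader"])
        .pivot_table(index="leader", columns="sample", aggfunc="size", fill_value=0)
    )
    counts = tab.reindex(
        index=[g.leader for g in groups], columns=list(design.all_samples), fill_value=0
    ).fillna(0).astype(int)
    counts.index.name = "accession"
    counts.columns.name = None
    return counts, excluded


def nsaf_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """NSAF: length-normalised spectral abundance factors, each sample
    column summing to 1. Raises on all-zero sample columns (naming the
    sample) and on missing or non-positive lengths."""
    L = lengths.reindex(counts.index)
    if L.isna().any():
        raise ValueError(f"missing lengths for: {list(counts.index[L.isna()])[:5]}")
    if (L <= 0).any():
        raise ValueError("all protein lengths must be > 0")
    saf = counts.div(L, axis=0)
    colsum = saf.sum(axis=0)
    dead = colsum[colsum == 0]
    if len(dead):
        raise ValueError(f"sample(s) with all-zero counts: {list(dead.index)}")
    return saf.div(colsum, axis=1)


@dataclass
class DetectionPartition:
    """Replicated-detection sets and their Venn decomposition.

    A protein is detected in a group when it has non-zero counts in at
    least ``min_replicates`` of the group's samples. ``cells`` keys are
    tuples of group names (in design order) and partition the detected
    proteins disjointly. ``exclusives`` additionally require strictly zero
    counts in every sample of all other groups.
    """

    detected: dict[str, set[str]]
    cells: dict[tuple[str, ...], set[str]]
    exclusives: dict[str, str]
    min_replicates: int

    @property
    def all_detected(self) -> set[str]:
        out: set[str] = set()
        for s in self.detected.values():
            out |= s
        return out


def detection_partition(
    counts: pd.DataFrame, design: StudyDesign, min_replicates: int = 2
) -> DetectionPartition:
    for g in design.group_names:
        if len(design.samples_of(g)) < min_replicates:
            raise ValueError(f"group {g!r} has fewer than {min_replicates} samples")
    detected: dict[str, set[str]] = {}
    for g in design.group_names:
        sub = counts[list(design.samples_of(g))]
        detected[g] = set(counts.index[(sub > 0).sum(axis=1) >= min_replicates])
    cells: dict[tuple[str, ...], set[str]] = {}
    for acc in sorted(set().union(*detected.values())) if detected else []:
        key = tuple(g for g in design.group_names if acc in detected[g])
        cells.setdefault(key, set()).add(acc)
    exclusives: dict[str, str] = {}
    for key, accs in cells.items():
        if len(key) != 1:
            continue
        own = key[0]
        other_samples = [s for g in design.group_names if g != own for s in design.samples_of(g)]
        for acc in accs:
            if counts.loc[acc, other_samples].sum() == 0:
                exclusives[acc] = own
    return DetectionPartition(
        detected=detected, cells=cells, exclusives=exclusives, min_replicates=min_replicates
    )


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("accession").to_csv(path, sep="\t", float_format="%.12g")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="accession")
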