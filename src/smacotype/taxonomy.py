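"""ICTV-style demarcation taxonomy for smacovirus-like genomes.

Species: single-linkage clusters at >= 77% genome-wide pairwise
nucleotide identity (the ICTV smacovirus species criterion); clustering
is the connected-component closure of the >=-threshold graph, so the
criterion stays pairwise while species remain well-defined groups.
Complete linkage is available as an option.

Genus: a species is placed in the genus of its best reference Rep match
at >= 40% amino-acid identity (direct evidence).  A genome below the
threshold inherits the genus of a directly-assigned member of its own
species cluster (transitive evidence), mirroring how closely-related
species share a genus; an optional within-study Rep identity matrix
allows a nearest-classified-species fallback.  Threshold comparisons are
inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .identity import PairwiseIdentityMatrix

log = logging.getLogger(__name__)

SPECIES_THRESHOLD = 77.0   # % genome-wide nucleotide identity
GENUS_THRESHOLD = 40.0     # % Rep amino-acid identity


@dataclass(frozen=True)
class SpeciesClustering:
    threshold: float
    clusters: tuple[tuple[str, ...], ...]  # sorted members, clusters sorted by first member
    linkage: str = "single"

    @property
    def species_of(self) -> dict[str, str]:
        return {m: cl[0] for cl in self.clusters for m in cl}

    def species_id(self, label: str) -> str:
        """Deterministic species id: the lexicographically smallest member."""
        return self.species_of[label]

    def cluster_of(self, label: str) -> tuple[str, ...]:
        for cl in self.clusters:
            if label in cl:
                return cl
        raise KeyError(label)


def cluster_species(
    m: PairwiseIdentityMatrix,
    threshold: float = SPECIES_THRESHOLD,
    linkage: str = "single",
) -> SpeciesClustering:
    """Partition genomes into species at the identity threshold.

    single: connected components of the graph with an edge wherever
    identity >= threshold (any chain of >=-threshold pairs merges).
    complete: hierarchical complete linkage cut so every within-cluster
    pair meets the threshold.
    """
    if m.space != "nucleotide":
        raise ValueError("species demarcation uses nucleotide identity")
    if not np.all(np.isfinite(m.values)):
        raise ValueError("incomplete identity matrix")
    labels = list(m.labels)
    if linkage == "single":
        g = nx.Graph()
        g.add_nodes_from(labels)
        n = len(labels)
        for i in range(n):
            for j in range(i + 1, n):
                if m.values[i, j] >= threshold:
                    g.add_edge(labels[i], labels[j])
        comps = [tuple(sorted(c)) for c in nx.connected_components(g)]
    elif linkage == "complete":
        dist = 100.0 - m.values
        np.fill_diagonal(dist, 0.0)
        z = hierarchy.complete(squareform(dist, checks=False))
        flat = hierarchy.fcluster(z, t=100.0 - threshold, criterion="distance")
        groups: dict[int, list[str]] = {}
        for lab, cid in zip(labels, flat):
            groups.setdefault(int(cid), []).append(lab)
        comps = [tuple(sorted(v)) for v in groups.values()]
    else:
        raise ValueError(f"unknown linkage {linkage!r}")
    comps.sort(key=lambda c: c[0])
    return SpeciesClustering(threshold, tuple(comps), linkage)


@dataclass(frozen=True)
class GenusAssignment:
    genome: str
    species_id: str
    genus: str                      # genus name or "unassigned"
    evidence: str                   # direct | transitive | none
    best_ref: tuple[str, float] | None = None
    rule: str = ""                  # which transitive rule fired, if any


def assign_genus(
    clust: SpeciesClustering,
    rep_ident_to_refs: dict[str, list[tuple[str, str, float]]],
    threshold: float = GENUS_THRESHOLD,
    study_rep_identity: PairwiseIdentityMatrix | None = None,
) -> list[GenusAssignment]:
    """Assign each clustered genome (and hence each species) to a genus.

    ``rep_ident_to_refs`` maps genome label -> [(reference label, genus,
    percent Rep aa identity), ...].  Direct: best reference >= threshold
    (inclusive); conflicting direct genera within a genome resolve to the
    higher percent with a logged warning.  Transitive: the genus of a
    directly-assigned member of the same species cluster (highest such
    percent); failing that, with ``study_rep_identity`` given, the genus
    of the nearest directly-classified species by within-study Rep
    identity.  Otherwise unassigned.
    """
    direct: dict[str, GenusAssignment] = {}
    pending: list[str] = []
    for cl in clust.clusters:
        for g in cl:
            comps = sorted(
                rep_ident_to_refs.get(g, []), key=lambda t: -t[2]
            )
            hits = [c for c in comps if c[2] >= threshold]
            if hits:
                genera = {c[1] for c in hits}
                if len(genera) > 1:
                    log.warning(
                        "%s: conflicting direct genus evidence %s; using best hit",
                        g, sorted(genera),
                    )
                ref, genus, pct = hits[0]
                direct[g] = GenusAssignment(
                    g, clust.species_id(g), genus, "direct", (ref, pct)
                )
            else:
                pending.append(g)

    out = dict(direct)
    for g in pending:
        sp = clust.species_id(g)
        mates = [
            direct[m] for m in clust.cluster_of(g) if m != g and m in direct
        ]
        if mates:
            anchor = max(mates, key=lambda a: a.best_ref[1])
            out[g] = GenusAssignment(
                g, sp, anchor.genus, "transitive", anchor.best_ref,
                rule="same-cluster",
            )
            continue
        if study_rep_identity is not None:
            best: tuple[float, GenusAssignment] | None = None
            for m, a in direct.items():
                try:
                    v = study_rep_identity.get(g, m)
                except ValueError:
                    continue
                if best is None or v > best[0]:
                    best = (v, a)
            if best is not None:
                out[g] = GenusAssignment(
                    g, sp, best[1].genus, "transitive", best[1].best_ref,
                    rule="nearest-classified-species",
                )
                continue
        comps = sorted(rep_ident_to_refs.get(g, []), key=lambda t: -t[2])
        out[g] = GenusAssignment(
            g, sp, "unassigned", "none",
            (comps[0][0], comps[0][2]) if comps else None,
        )
    return [out[g] for cl in clust.clusters for g in cl]


def species_genus_table(assignments: list[GenusAssignment]) -> dict[str, str]:
    """Collapse genome-level assignments to one genus per species id
    (directly-evidenced genus wins; 'unassigned' only if no member has
    one)."""
    per_species: dict[str, str] = {}
    for a in assignments:
        cur = per_species.get(a.species_id)
        if cur is None or (cur == "unassigned" and a.genus != "unassigned"):
            per_species[a.species_id] = a.genus
    return per_species
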