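"""Bundled reported values for the Zambian non-human-primate smacovirus
dataset (accessions LC386195-LC386205).

Three small tables ship with the package: the per-genome feature table
(genome length, Rep/CP protein lengths, nonanucleotide and Rep motif
strings), the reported within-study closest-pair genome identities, and
the reported best-reference Rep identities with the references' genera.
They serve as regression fixtures for the motif scanner and as inputs
for the demarcation taxonomy when the genome sequences themselves are
not at hand (fetching the accessions needs network access; see
``scripts/fetch_study_genomes.py`` in the repository).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .identity import PairwiseIdentityMatrix

TYPE_V_ACCESSION = "LC386203"  # unisense genome, excluded from demarcation


def _read(name: str) -> pd.DataFrame:
    with resources.files("smacotype.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def feature_table() -> pd.DataFrame:
    """Reported genome features for the 11 study genomes."""
    return _read("zm_smacovirus_features.tsv")


def reported_pair_identities() -> pd.DataFrame:
    """Reported within-study closest-pair genome nucleotide identities
    for the ten ambisense genomes."""
    return _read("zm_smacovirus_pair_identities.tsv")


def reported_identity_matrix(default: float = 0.0) -> PairwiseIdentityMatrix:
    """Identity matrix over the ten ambisense study genomes built from the
    reported closest-pair values; unreported pairs (all below the species
    threshold in the source data) default to ``default``."""
    df = reported_pair_identities()
    labels = sorted(set(df["a"]) | set(df["b"]))
    pairs = {
        (r.a, r.b): float(r.identity_nt) for r in df.itertuples(index=False)
    }
    return PairwiseIdentityMatrix.from_pairs(
        labels, pairs, space="nucleotide", default=default
    )


def reference_rep_identities() -> dict[str, list[tuple[str, str, float]]]:
    """Reported best-reference Rep amino-acid identities, as the mapping
    genome -> [(reference label, genus, percent)] consumed by
    :func:`smacotype.taxonomy.assign_genus`."""
    df = _read("zm_smacovirus_reference_rep_identities.tsv")
    out: dict[str, list[tuple[str, str, float]]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.genome, []).append(
            (r.reference_accession, r.reference_genus, float(r.rep_identity_aa))
        )
    return out
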