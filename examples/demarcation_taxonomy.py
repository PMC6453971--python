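"""Species and genus demarcation from reported identity values.

Uses the identity values bundled with the package for the Zambian
non-human-primate smacovirus dataset (accessions LC386195-LC386205):
within-study closest-pair genome nucleotide identities and best-reference
Rep amino-acid identities.  Species are single-linkage clusters at >= 77%
genome-wide nucleotide identity; each species takes the genus of its best
Rep reference at >= 40% amino-acid identity, with genomes below that
threshold inheriting transitively from a directly-assigned cluster mate.
"""

from collections import Counter

import smacotype as st
from smacotype import studydata

matrix = studydata.reported_identity_matrix()
clusters = st.cluster_species(matrix, threshold=77.0)
print(f"{len(clusters.clusters)} species among {len(matrix.labels)} "
      "ambisense genomes (the unisense genome is excluded):")
for members in clusters.clusters:
    print("  species:", ", ".join(members))

assignments = st.assign_genus(
    clusters, studydata.reference_rep_identities(), threshold=40.0
)
print("\ngenus assignments (per genome):")
for a in assignments:
    ref = f"{a.best_ref[0]} @ {a.best_ref[1]:.2f}%" if a.best_ref else "-"
    rule = f" [{a.rule}]" if a.rule else ""
    print(f"  {a.genome}: {a.genus} ({a.evidence}{rule}; best ref {ref})")

counts = Counter(st.species_genus_table(assignments).values())
print(f"\nspecies-level tally: {dict(counts)}")
print("Four Porprismacovirus species and one Huchismacovirus species — "
      "the two genomes below 40% are rescued transitively by their "
      "cluster mates.")
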