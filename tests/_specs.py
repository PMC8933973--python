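"""Shared community specifications for the test suite."""

from pepcover import CommunitySpec, FamilySpec

SMALL_SPEC = CommunitySpec(
    n_mags=8,
    phyla=(("Firmicutes", 0.5), ("Bacteroidetes", 0.5)),
    families=(
        FamilySpec("GH13", n_members=6, ec_numbers=("3.2.1.1",)),
        FamilySpec("GH3", n_members=6, ec_numbers=("3.2.1.21",)),
    ),
    background_proteins_per_mag=(10, 15),
    protein_length=(60, 150),
    seed=7,
)

# The study condition for planted-peptide recovery: 3 families of 20 members
# spread over 50 MAGs, one planted block per family.
RECOVERY_SPEC = CommunitySpec(seed=11)
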