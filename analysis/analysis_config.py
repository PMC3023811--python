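"""Shared study conditions for the numbered analysis drivers."""

from chprofile import SyntheticConfig


def study_config(seed: int) -> SyntheticConfig:
    """The synthetic study every driver works from.

    6,000 genes (a scaled universe preserving the statistical structure),
    quadruplicate GFP+/GFP- arrays at three timepoints, cumulative onset
    fractions sized to give a few hundred enriched genes per timepoint, a
    mutant genotype abolishing 80% of planted effects, and three planted
    gene sets shaped like the curated cilia/X-box collections (28 members at
    80% DE overlap, 750 at 10%, 83 at 20%).
    """
    return SyntheticConfig(
        n_genes=6000,
        onset_fractions=(0.023, 0.010, 0.007),
        geneset_spec=((28, 0.8), (750, 0.1), (83, 0.2)),
        include_mutant=True,
        promoter_length=1000,
        motif_plant_rate=0.5,
        background_motif_rate=0.05,
        seed=seed,
    )
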