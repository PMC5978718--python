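"""The study configuration shared by the numbered analysis scripts.

One native coastline (15 populations, 6 of them the genetically
identified invasion source) and three invaded coastlines of 10
populations each, mirroring the replicate continental invasions; 16
thalli genotyped per population with 25% planted clonal replicates and
10% haploids.
"""

from nicheshift.pipeline import RunConfig
from nicheshift.synthetic_world import GenoSimParams, WorldConfig


def study_config(seed: int, outdir: str, **overrides) -> RunConfig:
    defaults = dict(
        seed=seed,
        outdir=outdir,
        world=WorldConfig(n_invaded_coastlines=3),
        genotypes=GenoSimParams(clone_fraction=0.25, haploid_fraction=0.10),
    )
    defaults.update(overrides)
    return RunConfig(**defaults)
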