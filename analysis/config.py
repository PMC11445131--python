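"""Shared study conditions for the numbered analysis scripts.

The synthetic cohort mirrors the stratified muscle design: 803 samples
across six sex x age strata (F: 39/134/87, M: 93/245/205), 600 genes of
which 180 sit in twelve 15-gene co-expression modules — six active in a
single stratum (one per stratum) and six active everywhere.  Networks
are size-matched at k = 1,000 edges — the protocol's top-k idea at desk
scale, chosen below the DPI-surviving edge count of every stratum so all
six networks really are the same size, and small relative to the gene
universe so unique subnetworks stay sparse enough for over-representation
to discriminate; null tests use 10,000 bootstrap replicates.
"""

from pathlib import Path

from coexpnet import InferenceConfig, SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"

TOP_K = 1_000
N_SIMS = 10_000
FDR = 0.05


def simulation_config(seed: int = 1) -> SimulationConfig:
    return SimulationConfig(
        n_genes=600,
        n_modules=12,
        module_size=15,
        beta=1.5,
        stratum_specific_fraction=0.5,
        seed=seed,
    )


def inference_config() -> InferenceConfig:
    # DPI tolerance 0.2: in the latent-factor generator all within-module
    # edges have near-equal MI, so strict (eps=0) DPI removes the planted
    # direct edges themselves; a 20% tolerance spares edges whose MI is
    # within 20% of the strongest alternative path while still pruning
    # weakly supported triangles.
    return InferenceConfig(k=TOP_K, dpi_tolerance=0.2)
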