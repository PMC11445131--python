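"""Infer one MI co-expression network per stratum.

For each of the six expression matrices: all-pairs plug-in mutual
information on quantile-binned values, DPI pruning of indirect edges,
and retention of the k strongest interactions so all networks are
size-matched and comparable.
"""

import pandas as pd

from coexpnet import infer_network
from coexpnet.simulate import STRATA

from config import RESULTS, inference_config


def main() -> None:
    outdir = RESULTS / "networks"
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = inference_config()
    for label in STRATA:
        matrix = pd.read_csv(RESULTS / "strata" / f"{label}.tsv",
                             sep="\t", index_col=0)
        net = infer_network(matrix, cfg, name=label)
        net.write_tsv(outdir / f"{label}.tsv")
        print(f"{label}: {len(net)} edges over {len(net.genes)} genes "
              f"(strongest MI {max(net.edges.values()):.3f} nats)")


if __name__ == "__main__":
    main()
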