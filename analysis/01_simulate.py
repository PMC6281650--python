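"""Generate the synthetic input bundle.

Writes a complete set of pipeline inputs to results/bundle: eight
probe-statistic tables (seven murine models, one human), the literature
co-occurrence corpus, the mouse-to-human orthologue map, pathway gene sets
and the platform universe. The world contains 5 planted hub genes with a
10x boosted co-occurrence propensity — the ground truth later steps should
recover.
"""

import sys
from pathlib import Path

from dpnnet import io
from dpnnet.simulate import SyntheticConfig, generate_bundle

OUT = Path(__file__).resolve().parent.parent / "results" / "bundle"


def main(seed: int = 0) -> None:
    config = SyntheticConfig(seed=seed)
    bundle = generate_bundle(config)
    io.write_bundle(bundle, OUT)
    print(f"universe: {config.n_genes} genes; "
          f"datasets: {[len(d) for d in bundle.deg_sets]} DEGs "
          f"(labels {list(config.dataset_labels)})")
    print(f"corpus: {len(bundle.corpus)} co-occurrence edges")
    print(f"orthologue map: {len(bundle.orthologue_map)} pairs "
          f"({config.orthologue_dropout:.0%} dropout, hubs exempt)")
    print(f"planted hubs: {bundle.hubs} (signs {bundle.hub_signs})")
    print(f"bundle written to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
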