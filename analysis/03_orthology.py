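#!/usr/bin/env python
"""Reciprocal-best-hit orthology of the accepted reference hits across the
other 12 species (local alignment, E <= 1e-10 cutoff), the conservation
matrix, and the cross-phylum intersection.

The intersection should equal the six families planted with seed sets in
both query phyla — the synthetic analog of the clock components common to
mammals, insects and nematodes.
"""

import sys
from pathlib import Path

from nemaclock.pipeline import PipelineConfig, run

OUT = Path(__file__).resolve().parent.parent / "results" / "pipeline"


def main(seed: int = 0) -> None:
    config = PipelineConfig(seed=seed, output_dir=str(OUT))
    run(config, until="orthology")
    common = [
        ln.split("\t")[0]
        for ln in list(open(OUT / "intersection.tsv"))[1:]
        if ln.split("\t")[1] == "1"
    ]
    print(f"fully conserved cross-phylum loci ({len(common)}): {', '.join(sorted(common))}")
    print(f"conservation matrix: {OUT}/conservation.tsv")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
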