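#!/usr/bin/env python
"""Extract the 3000 bp upstream of each reference clock-gene analog's ATG and
scan both strands for the eight circadian cis-elements (E-box, D-box, RRE,
GRE, PPRE, CREB, HSE, CBP) in IUPAC degenerate syntax.

On the scrubbed synthetic genome every reported match lies inside a planted
footprint, so the match table doubles as an exactness check of the scanner.
"""

import sys
from pathlib import Path

from nemaclock.pipeline import PipelineConfig, run

OUT = Path(__file__).resolve().parent.parent / "results" / "pipeline"


def main(seed: int = 0) -> None:
    config = PipelineConfig(seed=seed, output_dir=str(OUT))
    run(config, until="promoters")
    rows = [ln for ln in open(OUT / "motif_matches.tsv") if not ln.startswith("#")]
    print(f"{len(rows) - 1} motif occurrences (motif_matches.tsv, BED in motif_matches.bed):")
    for ln in rows:
        print("  " + ln.rstrip())


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
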