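#!/usr/bin/env python
"""Plate quality control and normalisation of the simulated screen.

Computes per-plate Z-prime from the negative (untreated) and positive
(full-kill) controls, then converts raw RFU to percent viability by control
normalisation and aggregates technical and biological replicates.
"""

from pathlib import Path

from aafscreen import io as aio
from aafscreen import pipeline, plates

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    wells = aio.read_wells(RESULTS / "screen_wells.csv")

    qc = plates.plate_qc(wells)
    qc.to_csv(RESULTS / "plate_qc.csv", index=False)
    print(f"plate QC: {qc.pass_flag.sum()}/{len(qc)} plates pass "
          f"(Z' >= 0.5); median Z' = {qc.z_prime.median():.3f}")

    points = pipeline.screen_viability(wells, mode="controls")
    points.to_csv(RESULTS / "viability_points.csv", index=False)
    print(f"normalised viability for {len(points)} "
          "(condition, drug, dose) points written")


if __name__ == "__main__":
    main()
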