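#!/usr/bin/env python
"""Generate the synthetic drug screen emulating the study design.

5 ovarian-cancer cell lines x (media + 5 ascites conditions) = 30
conditions, 11 drugs (carboplatin + paclitaxel as standard of care, 9
repurposed), 8-point half-log titrations, 3 technical x 2 biological
replicates on 384-well plates with 5% multiplicative signal noise.  One
ascites condition ("A19") carries a strong resistance phenotype (10x
midpoint shift, 50-point efficacy loss); the others carry mild random
shifts.  Writes the well table, per-plate gains and the ground truth.
"""

from pathlib import Path

from aafscreen import io as aio
from aafscreen.synthetic import ScreenConfig, default_truth, generate_screen

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20240908


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    config = ScreenConfig(seed=SEED)
    truth = default_truth(config)
    wells, plate_gains = generate_screen(config, truth)

    aio.write_config(config, RESULTS / "screen_config.yaml")
    aio.write_truth(truth, RESULTS / "screen_truth.csv")
    aio.write_wells(wells, RESULTS / "screen_wells.csv")
    plate_gains.to_csv(RESULTS / "plate_gains.csv", index=False)

    n_cond = len(config.cell_lines) * len(config.media_conditions)
    print(f"generated {len(wells)} wells on {len(plate_gains)} plates")
    print(f"{n_cond} conditions x {len(config.drugs)} drugs, "
          f"{config.replicates_technical}x{config.replicates_biological} replicates")
    print(f"tables written under {RESULTS}")


if __name__ == "__main__":
    main()
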