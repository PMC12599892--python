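"""Simulate the full study's raw instrument data.

For every (group, condition, day) cell of the 3 x 2 x 3 design this writes:
nine OCE phase depth-time maps (three independent experiments in triplicate,
HDF5) whose true wave speeds follow the cell's effect structure, one
Brillouin spectrum per replicate, one brightfield-style spheroid image per
cell, plus the spectrometer calibration set and a ground-truth table for
later comparison.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from spheromech import io, synth
from spheromech.study import CONDITIONS, DAYS, GROUPS

N_REPLICATES = 9  # three independent experiments, each in triplicate


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results/raw"))
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(args.seed)
    speed_spec = synth.default_study_spec("wave_speed_mps", seed=args.seed)
    shift_spec = synth.default_study_spec("brillouin_shift_ghz", seed=args.seed + 1)

    # --- OCE maps: triplicate per cell, replicate speeds jittered at the spec CV
    truth_rows = []
    oce_path = args.outdir / "oce_maps.h5"
    if oce_path.exists():
        oce_path.unlink()
    sigma = np.sqrt(np.log(1 + speed_spec.cv**2))
    for group in GROUPS:
        for condition in CONDITIONS:
            for day in DAYS:
                mean_speed = (
                    speed_spec.baselines[(group, condition)]
                    * speed_spec.day_factors[(group, condition)][day]
                )
                for rep in range(1, N_REPLICATES + 1):
                    speed = mean_speed * rng.lognormal(-sigma**2 / 2, sigma)
                    cfg = synth.OCESimConfig(
                        true_speed_mps=float(speed), seed=int(rng.integers(2**31))
                    )
                    m = synth.make_oce_phase_map(cfg)
                    io.save_map_h5(m, oce_path, dataset=f"{group}/{condition}/day{day}/rep{rep}")
                    truth_rows.append(
                        dict(group=group, condition=condition, day=day, replicate=rep,
                             metric="wave_speed_mps", true_value=float(speed))
                    )

    # --- Brillouin: calibration set + one spectrum per cell replicate
    materials = synth.default_calibration_shifts()
    base_cfg = synth.BrillouinSimConfig(noise_model="poisson", amplitude=400.0,
                                        baseline=50.0, seed=args.seed)
    cal_dir = args.outdir / "calibration"
    cal_dir.mkdir(exist_ok=True)
    for spec in synth.make_calibration_set(materials, base_cfg):
        io.save_spectrum_csv(spec, cal_dir / f"{spec.label}.csv")
    (cal_dir / "known_shifts.json").write_text(
        json.dumps({name: shift for name, shift in materials}, indent=2)
    )

    spec_dir = args.outdir / "spectra"
    spec_dir.mkdir(exist_ok=True)
    sigma_b = np.sqrt(np.log(1 + shift_spec.cv**2))
    for group in GROUPS:
        for condition in CONDITIONS:
            for day in DAYS:
                mean_shift = (
                    shift_spec.baselines[(group, condition)]
                    * shift_spec.day_factors[(group, condition)][day]
                )
                for rep in range(1, N_REPLICATES + 1):
                    shift = mean_shift * rng.lognormal(-sigma_b**2 / 2, sigma_b)
                    cfg = synth.BrillouinSimConfig(
                        true_shift_ghz=float(shift), noise_model="poisson",
                        amplitude=400.0, baseline=50.0, seed=int(rng.integers(2**31)),
                    )
                    spec = synth.make_brillouin_spectrum(cfg)
                    io.save_spectrum_csv(spec, spec_dir / f"{group}_{condition}_day{day}_rep{rep}.csv")
                    truth_rows.append(
                        dict(group=group, condition=condition, day=day, replicate=rep,
                             metric="brillouin_shift_ghz", true_value=float(shift))
                    )

    # --- spheroid images: size grows for controls, shrinks for treated
    img_dir = args.outdir / "images"
    img_dir.mkdir(exist_ok=True)
    size_factors = {"control": {0: 1.0, 4: 1.05, 7: 1.10}, "treated": {0: 1.0, 4: 0.90, 7: 0.80}}
    for group in GROUPS:
        for condition in CONDITIONS:
            d0 = 200.0  # px; 400 um at 2 um/px
            for day in DAYS:
                img = synth.make_spheroid_image(
                    d0 * size_factors[condition][day], image_size=512, noise_std=5.0,
                    seed=int(rng.integers(2**31)), acquisition_day=day,
                    sample_id=f"{group}_{condition}",
                )
                io.save_image_tiff(img.pixels, img_dir / f"{group}_{condition}_day{day}.tiff")
                truth_rows.append(
                    dict(group=group, condition=condition, day=day, replicate=1,
                         metric="eq_diameter_um",
                         true_value=float(img.metadata["ground_truth"]["diameter_px"] * 2.0))
                )

    truth = pd.DataFrame(truth_rows)
    truth.to_csv(args.outdir / "ground_truth.csv", index=False)
    print(f"wrote {len(truth_rows)} ground-truth records under {args.outdir}")
    print(f"  OCE maps: {3 * 2 * 3 * N_REPLICATES} in {oce_path.name}")
    print(f"  Brillouin spectra: {3 * 2 * 3 * N_REPLICATES} + {len(materials)} calibration")
    print(f"  spheroid images: {3 * 2 * 3}")


if __name__ == "__main__":
    main()
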