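"""Segment the spheroid images and track size relative to day 0.

Controls grow slightly over the week while treated spheroids shrink;
this script quantifies that from the images alone.
"""

import argparse
from pathlib import Path

import pandas as pd

from spheromech import imaging, io
from spheromech.imaging import SpheroidImage
from spheromech.study import CONDITIONS, DAYS, GROUPS


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--rawdir", type=Path, default=Path("results/raw"))
    parser.add_argument("--out", type=Path, default=Path("results/morphology.csv"))
    args = parser.parse_args()

    rows = []
    for group in GROUPS:
        for condition in CONDITIONS:
            by_day = {}
            for day in DAYS:
                pixels = io.load_image_tiff(args.rawdir / "images" / f"{group}_{condition}_day{day}.tiff")
                img = SpheroidImage(pixels, pixel_size_um=2.0, acquisition_day=day,
                                    sample_id=f"{group}_{condition}")
                by_day[day] = imaging.segment_spheroid(img)
            traj = imaging.track_size(by_day)
            for _, r in traj.iterrows():
                m = by_day[r.day]
                rows.append(
                    dict(sample_id=f"{group}_{condition}", group=group, condition=condition,
                         day=int(r.day), area_um2=m.area_um2,
                         eq_diameter_um=m.equivalent_diameter_um,
                         circularity=m.circularity, relative_size=r.relative_size))

    out = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(args.out, index=False)
    d7 = out[out.day == 7].groupby("condition").relative_size.mean()
    print(f"segmented {len(out)} images -> {args.out}")
    print(f"day-7 size vs day 0: control x{d7['control']:.2f}, treated x{d7['treated']:.2f}")


if __name__ == "__main__":
    main()
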