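"""Pixel-as-event subset mapping of the synthetic tissue image.

Stitch (single-tile identity here), denoise, convert pixels to events,
classify in two stages, write per-subset masks, the pseudocolour composite
and spatial statistics, and check pixel/suspension concordance on the
held-out markers CD45RB and CD24.

Reads results/data/, writes results/imc/.
"""

from pathlib import Path

import numpy as np
import tifffile

from mzatlas import imc, synthetic
from mzatlas.panels import PANEL
from mzatlas.pipeline import stage_seed

SEED = stage_seed(1, "imc")
DATA = Path("results/data")
OUT = Path("results/imc")
OUT.mkdir(parents=True, exist_ok=True)

img, chans = synthetic.read_image(DATA / "tissue_image.tiff")
truth = {p.stem.replace("truth_", ""): tifffile.imread(p).astype(bool)
         for p in sorted(DATA.glob("truth_*.tiff"))}

# clean very low intensities (well below any archetype signal)
img = imc.denoise_threshold(img, chans, {c: 0.05 for c in chans})
events = imc.pixels_to_events(img, chans)
labels = imc.classify_pixels(events, seed=SEED)
print("pixel classification:",
      dict(labels.value_counts().sort_values(ascending=False)))

xs = events.data["x"].to_numpy()
ys = events.data["y"].to_numpy()
masks = imc.masks_from_labels(labels, xs, ys, img.shape[:2])
for name, mask in masks.items():
    synthetic.write_mask(mask, OUT / f"mask_{name}.tiff")
comp = imc.composite_image(masks, img.shape[:2])
tifffile.imwrite(OUT / "composite.tiff", (comp * 255).astype(np.uint8))

for zone, lab in [("gc", "gc"), ("mz", "mz"), ("memory", "csm"),
                  ("naive", "naive")]:
    j = (masks[lab] & truth[zone]).sum() / (masks[lab] | truth[zone]).sum()
    print(f"  {lab:>6s} vs truth {zone}: Jaccard = {j:.3f}")

summary = imc.spatial_summary(masks, {"gc": truth["gc"],
                                      "epithelium": truth["epithelium"]})
summary.to_csv(OUT / "spatial_summary.tsv", sep="\t", index=False)
s = summary.set_index(["subset", "reference"])["mean"]
print(f"mean distance to GC boundary: MZ {s[('mz', 'gc')]:.0f} px "
      f"vs class-switched memory {s[('csm', 'gc')]:.0f} px")
print(f"mean distance to epithelium: memory {s[('csm', 'epithelium')]:.0f} px "
      f"vs MZ {s[('mz', 'epithelium')]:.0f} px")

# held-out marker concordance against the suspension arm
keep = (labels != "other").to_numpy()
pix = events.data.loc[keep].copy()
pix["subset"] = labels[keep].to_numpy()
pixel_prof = pix.groupby("subset")[["CD45RB", "CD24"]].median()
susp = synthetic.read_event_csv(DATA / "cytometry_events.csv", PANEL)
susp_prof = susp.data.groupby("truth_subset")[["CD45RB", "CD24"]].median()
susp_prof = susp_prof.rename(index={"csm_igg": "csm"})
conc = imc.validate_against_suspension(pixel_prof, susp_prof)
conc.to_csv(OUT / "suspension_concordance.tsv", sep="\t", index=False)
print(conc.to_string(index=False))
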