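"""Generate the digital PET phantom set: one baseline scan with a 25 mm
tumor lesion and a kidney-like physiological hot spot, plus interim scans
whose lesion volume is scaled by 0.2 / 1.0 / 2.0 (the three response
scenarios).  NIfTI volumes go to scratch/phantoms/ (binary); the ground
truth and a summary go to results/.
"""

import json
from pathlib import Path

from netmtv import generate_interim_phantom, generate_phantom, paper_like_phantom_config
from netmtv.petvol import write_mask, write_volume

SEED = 7
FACTORS = (0.2, 1.0, 2.0)

out_img = Path("scratch/phantoms")
out_img.mkdir(parents=True, exist_ok=True)
out_res = Path("results")
out_res.mkdir(exist_ok=True)

cfg = paper_like_phantom_config(seed=SEED)
vol, excl, truth = generate_phantom(cfg)
write_volume(vol, out_img / "baseline.nii.gz")
write_mask(excl, cfg.spacing, out_img / "exclusion.nii.gz")

summary = {
    "seed": SEED,
    "grid_shape": list(cfg.grid_shape),
    "spacing_mm": list(cfg.spacing),
    "liver_mean_suv": cfg.liver_mean,
    "liver_sd_suv": cfg.liver_sd,
    "liver_voi_center_mm": list(truth.liver_voi_center),
    "true_lesion_volumes_ml": list(truth.lesion_volumes_ml),
    "interim": {},
}
for f in FACTORS:
    vol_i, excl_i, truth_i = generate_interim_phantom(cfg, (f,))
    tag = f"interim_x{f:g}"
    write_volume(vol_i, out_img / f"{tag}.nii.gz")
    write_mask(excl_i, cfg.spacing, out_img / f"{tag}_exclusion.nii.gz")
    summary["interim"][tag] = {
        "volume_scale_factor": f,
        "true_lesion_volumes_ml": list(truth_i.lesion_volumes_ml),
    }

(out_res / "phantom_truth.json").write_text(json.dumps(summary, indent=2))
print(f"baseline lesion: {truth.lesion_volumes_ml[0]:.2f} ml (true)")
for tag, block in summary["interim"].items():
    vols = block["true_lesion_volumes_ml"]
    print(f"{tag}: true lesion volume {vols[0]:.2f} ml" if vols else f"{tag}: lesion removed")
print(f"volumes in {out_img}/, truth in {out_res}/phantom_truth.json")
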