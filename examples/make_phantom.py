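"""Generate a synthetic multi-contrast head phantom and write it to disk.

Produces paired ZTE / black-bone / FIESTA-C volumes of the same digital
head on their clinical acquisition grids, plus ground-truth masks and a
JSON sidecar — the same thing `ztebone phantom --spec sinus --out DIR` does.
"""

from pathlib import Path

from ztebone import default_specs, generate_phantom, write_volume

out = Path("scratch/phantom_sinus")
out.mkdir(parents=True, exist_ok=True)

phantom = generate_phantom(default_specs()["sinus"])

for modality, volume in phantom.volumes.items():
    write_volume(volume, out / f"{modality}.nii")
    write_volume(phantom.truth(modality, "bone"), out / f"truth_bone_{modality}.nii")
    shape = "x".join(str(s) for s in volume.grid.shape)
    spacing = " x ".join(f"{s:.1f}" for s in volume.grid.spacing)
    print(f"{modality:>7}: {shape} voxels at {spacing} mm, "
          f"bone truth {phantom.truth(modality, 'bone').count} voxels")

print(f"\nWritten to {out}/ — each modality samples the same head on its own")
print("grid; truth masks come from one master label volume, so they agree")
print("across resolutions up to slice quantisation.")
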