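"""Generate a synthetic endoscopy corpus and inspect its structure.

Builds the default desk-scale corpus (3 lesion classes, 30 patients per class,
5 frames per patient at 64 x 64), prints its shape, and shows that the three
procedural textures occupy different spectral bands — the property that makes
the corpus classifiable and the training pipeline testable offline.
"""

import numpy as np

import polypclip as pc

samples, meta = pc.generate_dataset(pc.SyntheticConfig(seed=0))
print(f"{len(samples)} images over {meta['patient_id'].nunique()} patients")
print(meta.groupby("label")["patient_id"].nunique().rename("patients/class"))


def high_band(img, lo=6):
    g = img.mean(axis=2)
    F = np.abs(np.fft.fftshift(np.fft.fft2(g - g.mean())))
    n = g.shape[0]
    yy, xx = np.meshgrid(np.arange(n) - n // 2, np.arange(n) - n // 2, indexing="ij")
    return F[np.sqrt(xx**2 + yy**2) >= lo].mean()


for cls in pc.CLASSES:
    energies = [high_band(s.image) for s in samples if s.label == cls][:60]
    print(f"{cls:12s} mean high-band |FFT| = {np.mean(energies):.3f}")
# serrated hyperplastic texture is the finest, smooth normal mucosa the coarsest
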