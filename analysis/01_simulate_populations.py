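#!/usr/bin/env python
"""Simulate the four reporter populations used throughout the analysis.

One synthetic field of view per reporter variant, sized to the published
cell counts, with the phenotype each variant shows during infection:

  gfpmut1   n=111  fully imported   (nucleus/cytoplasm contrast 3)
  f99s      n=177  fully excluded   (contrast 0.2)
  m153t     n=115  50/50 mixture of mild imported/excluded (contrast 1.25)
  v163a     n=82   fully imported

Writes multi-page TIFFs plus ground-truth sidecars under results/scenes/.
"""

from pathlib import Path

from phagenuc.synth import make_population, render_scene, write_scene

OUT = Path(__file__).resolve().parent.parent / "results" / "scenes"

POPULATIONS = {
    "gfpmut1": dict(n=111, phenotype_mix={"imported": 1.0}, seed=101),
    "f99s": dict(n=177, phenotype_mix={"excluded": 1.0}, seed=102),
    "m153t": dict(
        n=115,
        phenotype_mix={"imported": 0.5, "excluded": 0.5},
        contrasts={"imported": 1.25, "excluded": 0.8},
        seed=103,
    ),
    "v163a": dict(n=82, phenotype_mix={"imported": 1.0}, seed=104),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, kw in POPULATIONS.items():
        n = kw.pop("n")
        spec = make_population(n, **kw)
        image, truth = render_scene(spec)
        spec.to_yaml(OUT / f"{name}.spec.yaml")
        write_scene(OUT, name, image, truth)
        print(f"{name}: {n} cells, image {image.shape[1]}x{image.shape[2]}, "
              f"phenotypes {truth.phenotype_counts}")


if __name__ == "__main__":
    main()
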