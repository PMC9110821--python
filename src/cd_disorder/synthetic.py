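"""Synthetic labeled CD spectra emulating the ordered/disordered classes.

Far-UV CD band shapes are emulated as sums of Gaussian bands in
delta-epsilon units. Four templates cover the spectral space the classifier
must handle:

* ``coil`` — disordered chains: an intense minimum near 200 nm and a weak
  signal around 222 nm;
* ``helix_rich`` — ordered, alpha-helical: positive band near 192 nm,
  double minima near 208 and 222 nm;
* ``sheet_rich`` — ordered, beta-sheet: positive band near 196 nm, single
  minimum near 217 nm;
* ``twisted_beta`` — ordered proteins rich in highly twisted antiparallel
  beta-sheets (protease inhibitors, SH3 domains...), whose coil-like deep
  ~200 nm minimum is the classical confounder for disorder detection; their
  curvature in the 210-230 nm region still separates them from true coils.

The band parameters are package constants chosen to satisfy the assertable
shape constraints below; they are *not* fits to any measured reference
spectra and carry no ground-truth claim. Generated sets add multiplicative
lognormal amplitude jitter (emulating concentration error) and i.i.d.
Gaussian point noise, and are bit-reproducible from a seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .reference_set import Label, LabeledSpectrumSet, write_manifest
from .spectra_io import CDSpectrum, Units, write_spectrum

#: Gaussian bands per template: (amplitude delta-eps, center nm, width nm).
TEMPLATE_BANDS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "coil": ((-5.3, 198.0, 8.5), (0.12, 224.0, 7.0)),
    "helix_rich": ((6.0, 191.0, 7.0), (-4.0, 208.0, 6.0), (-4.2, 222.0, 7.5)),
    "sheet_rich": ((3.0, 196.0, 6.0), (-2.2, 217.0, 8.0)),
    "twisted_beta": ((1.0, 185.0, 5.0), (-4.6, 199.0, 8.2), (-0.22, 227.0, 9.0)),
}

ORDERED_TEMPLATES = ("helix_rich", "sheet_rich", "twisted_beta")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a generated labeled set.

    ``amplitude_jitter`` is the lognormal sigma of a per-spectrum amplitude
    factor (0.15 corresponds to the ~15-20% concentration error typical of
    disordered-protein samples); ``point_noise_sigma`` is per-point Gaussian
    noise in delta-epsilon units. ``ordered_mix`` weights the three ordered
    templates; twisted-beta spectra are ORDERED, so the generated benchmark
    contains the confounder that makes the problem hard.
    """

    n_ordered: int = 60
    n_disordered: int = 40
    grid: tuple[float, float, float] = (175.0, 250.0, 1.0)
    amplitude_jitter: float = 0.15
    point_noise_sigma: float = 0.02
    ordered_mix: tuple[float, float, float] = (0.4, 0.35, 0.25)
    seed: int = 0

    def __post_init__(self):
        if self.n_ordered < 0 or self.n_disordered < 0:
            raise ValueError("counts must be >= 0")
        if self.amplitude_jitter < 0 or self.point_noise_sigma < 0:
            raise ValueError("jitter and noise must be >= 0")
        if abs(sum(self.ordered_mix) - 1.0) > 1e-9:
            raise ValueError("ordered_mix weights must sum to 1")
        lo, hi, step = self.grid
        if not (lo < hi and step > 0):
            raise ValueError("grid must be (lo < hi, step > 0)")


def _grid_array(grid) -> np.ndarray:
    lo, hi, step = grid
    return np.arange(lo, hi + step / 2, step)


def basis_spectrum(template: str, grid=(175.0, 250.0, 1.0)) -> CDSpectrum:
    """Deterministic noise-free template curve on the given grid.

    The templates satisfy, in delta-epsilon: coil has its global minimum
    within 198-202 nm with ``|value(222)| < 0.25 * |value(200)|``;
    helix_rich is positive at 192 nm and negative at 208/222 nm; sheet_rich
    is positive near 196 nm and negative near 217 nm; twisted_beta shares the
    coil's deep ~200 nm minimum but differs in 210-230 nm curvature.
    """
    if template not in TEMPLATE_BANDS:
        raise ValueError(
            f"unknown template {template!r}; choose from {sorted(TEMPLATE_BANDS)}"
        )
    wl = _grid_array(grid)
    values = np.zeros_like(wl)
    for amp, center, width in TEMPLATE_BANDS[template]:
        values += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return CDSpectrum(
        protein_id=f"template_{template}",
        wavelengths_nm=wl,
        values=values,
        units=Units.DELTA_EPSILON,
        source="synthetic",
    )


def generate_set(cfg: SyntheticConfig) -> LabeledSpectrumSet:
    """Generate a labeled synthetic set; same seed gives bit-identical output.

    Each spectrum is a class template (disordered: coil; ordered: drawn from
    ``ordered_mix``) times a lognormal amplitude factor, plus i.i.d. Gaussian
    point noise. Labels follow the template class, so twisted-beta confounders
    are labeled ORDERED.
    """
    rng = np.random.default_rng(cfg.seed)
    wl = _grid_array(cfg.grid)
    templates = {name: basis_spectrum(name, cfg.grid).values for name in TEMPLATE_BANDS}
    entries = []

    def _make(i, template, label):
        base = templates[template]
        # degenerate sigmas still consume draws, so configs that differ only
        # in jitter/noise levels see identical template assignments
        amp = rng.lognormal(mean=0.0, sigma=cfg.amplitude_jitter)
        noise = rng.normal(0.0, cfg.point_noise_sigma, size=wl.shape)
        values = base * amp + noise
        entries.append(
            (
                CDSpectrum(
                    protein_id=f"syn_{label.value[:3]}_{i:04d}_{template}",
                    wavelengths_nm=wl.copy(),
                    values=values,
                    units=Units.DELTA_EPSILON,
                    source="synthetic",
                ),
                label,
            )
        )

    mix = np.asarray(cfg.ordered_mix, dtype=float)
    for i in range(cfg.n_ordered):
        template = ORDERED_TEMPLATES[rng.choice(len(ORDERED_TEMPLATES), p=mix)]
        _make(i, template, Label.ORDERED)
    for i in range(cfg.n_disordered):
        _make(i, "coil", Label.DISORDERED)
    return LabeledSpectrumSet(entries)


def write_fixture_set(cfg: SyntheticConfig, outdir) -> str:
    """Generate a set, write two-column files plus a manifest; return its path.

    The files are consumed unchanged by the manifest loader, so the full
    read -> classify pipeline is testable with no external data.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    set_ = generate_set(cfg)
    paths = []
    for spec, _ in set_.entries:
        p = os.path.join(outdir, f"{spec.protein_id}.txt")
        write_spectrum(spec, p)
        paths.append(p)
    manifest = os.path.join(outdir, "manifest.csv")
    write_manifest(set_, manifest, paths, Units.DELTA_EPSILON)
    return manifest
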