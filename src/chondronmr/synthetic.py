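"""Synthetic data generators mirroring the statistical structure of the
experimental inputs, so every pipeline stage is testable offline.

* NOESY peak tables are generated from a known 3D structure through the same
  I = k r^-6 law the calibration inverts, with optional multiplicative
  log-normal intensity noise and 3:2 overlap grouping of the chemically
  equivalent beta(1->3)/beta(1->4) linkage peaks of the hexasaccharide.
* Amide shift-vs-temperature series are linear with Gaussian noise.
* The reference hexasaccharide fixture is a CN6 chain built at the ensemble
  average glycosidic torsions of the deposited structure; it is a synthetic
  stand-in for the deposited coordinates, not the deposition itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anneal import Conformer, ConformerEnsemble
from .errors import InputError, StructuralError
from .glycan import ChainBuilder, OligosaccharideModel
from .noe import CN6_REFERENCE_PAIRS, CN6_RESTRAINT_PAIRS, NoePeak
from .shifts import ShiftSeries, load_table


@dataclass
class SyntheticNoesyConfig:
    k_true: float = 1000.0  # intensity * A^6
    noise_model: str = "none"  # or "multiplicative-lognormal"
    noise_sd: float = 0.0  # fractional sd of the log-normal factor
    seed: int = 0
    overlap_grouping: bool = False

    def __post_init__(self):
        if self.k_true <= 0:
            raise InputError("k_true must be positive")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        if self.noise_model not in ("none", "multiplicative-lognormal"):
            raise InputError(f"unknown noise model {self.noise_model!r}")


def _noise_factors(config: SyntheticNoesyConfig, n: int, rng) -> np.ndarray:
    if config.noise_model == "none" or config.noise_sd == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(config.noise_sd ** 2))
    return rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=n)


def simulate_noesy(model: OligosaccharideModel, config: SyntheticNoesyConfig):
    """NOESY peak list for the CN6 reference + conformational pairs.

    Intensities follow I = k_true * r^-6 from the model's own distances.
    With overlap grouping the equivalent-linkage conformational peaks are
    summed (multiplicity 3 for beta(1->3), 2 for beta(1->4)); reference
    peaks are always resolved and carry their true distance for calibration.
    """
    rng = np.random.default_rng(config.seed)
    peaks = []

    ref_d = []
    for a, b in CN6_REFERENCE_PAIRS:
        try:
            ref_d.append(model.distance(a, b))
        except StructuralError as exc:
            raise StructuralError(f"reference pair {a}/{b} missing: {exc}") from exc
    conf_d = [model.distance(a, b) for _, _, a, b, _ in CN6_RESTRAINT_PAIRS]

    noise = _noise_factors(config, len(ref_d) + len(conf_d), rng)
    for (a, b), r, f in zip(CN6_REFERENCE_PAIRS, ref_d, noise[: len(ref_d)]):
        peaks.append(
            NoePeak(atom_a=a, atom_b=b, intensity=config.k_true * r ** -6.0 * f,
                    overlap_multiplicity=1, role="reference", known_distance=r)
        )

    conf_noise = noise[len(ref_d):]
    if not config.overlap_grouping:
        for (lk, lt, a, b, _), r, f in zip(CN6_RESTRAINT_PAIRS, conf_d, conf_noise):
            peaks.append(
                NoePeak(atom_a=a, atom_b=b, intensity=config.k_true * r ** -6.0 * f,
                        overlap_multiplicity=1, role="conformational")
            )
        return peaks

    # group equivalent-linkage peaks: same linkage type + atom-name pair
    groups = {}
    for i, (lk, lt, a, b, _) in enumerate(CN6_RESTRAINT_PAIRS):
        name_pair = (lt, a.split(":")[1], b.split(":")[1])
        groups.setdefault(name_pair, []).append(i)
    for members in groups.values():
        total = sum(
            config.k_true * conf_d[i] ** -6.0 * conf_noise[i] for i in members
        )
        mult = len(members)
        for i in members:
            lk, lt, a, b, _ = CN6_RESTRAINT_PAIRS[i]
            peaks.append(
                NoePeak(atom_a=a, atom_b=b, intensity=total,
                        overlap_multiplicity=mult, role="conformational")
            )
    return peaks


def simulate_shift_series(slope_true: float, intercept: float, temps,
                          noise_sd: float = 0.0, seed: int = 0,
                          key: str = "synthetic") -> ShiftSeries:
    """Linear shift series delta(T) = intercept + slope_true*T/1000 + noise.

    slope_true is in ppb/degC, intercept in ppm at 0 degC, noise_sd in ppm.
    """
    temps = list(temps)
    if len(temps) < 2:
        raise InputError("need at least two temperatures")
    rng = np.random.default_rng(seed)
    pts = [
        (float(t), intercept + slope_true * t / 1000.0
         + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
        for t in temps
    ]
    return ShiftSeries(key=key, points=pts)


def reference_torsion_fixture(builder: ChainBuilder = None) -> OligosaccharideModel:
    """Pseudo-deposited CN6: the chain built at the ensemble-average
    glycosidic torsions (packaged table7 fixture).  Synthetic stand-in for
    the deposited coordinates; used as ground truth for NOESY simulation and
    analysis round-trips."""
    table = load_table("table7_torsions")
    builder = builder or ChainBuilder(6)
    torsions = [
        (float(row.phi_mean), float(row.psi_mean)) for _, row in table.iterrows()
    ]
    return builder.model(torsions)


def perturb_ensemble(model: OligosaccharideModel, torsion_jitter_sd: float,
                     n: int, seed: int = 0) -> ConformerEnsemble:
    """n copies of `model` with Gaussian jitter on every glycosidic torsion.

    jitter 0 reproduces the input exactly; useful as a statistics fixture.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    from .glycan import measure_glycosidic_torsions

    base = np.array(
        [[phi, psi] for _, phi, psi in measure_glycosidic_torsions(model)]
    )
    builder = ChainBuilder(model.n_residues, anomer=model.anomer)
    rng = np.random.default_rng(seed)
    members = []
    for i in range(n):
        jitter = (
            rng.normal(0.0, torsion_jitter_sd, size=base.shape)
            if torsion_jitter_sd > 0
            else np.zeros_like(base)
        )
        tors = base + jitter
        m = builder.model([tuple(t) for t in tors], check_clashes=False)
        members.append(Conformer(model=m, energy=0.0, max_violation=0.0,
                                 seed_index=i, torsions=tors))
    return ConformerEnsemble(models=members, n_generated=n, kept_fraction=1.0)
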