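"""NOESY intensity -> distance calibration and restraint generation.

The isolated spin-pair approximation relates a NOESY cross-peak intensity I
to the internuclear distance r through I = k * r^-6.  The constant k is
fitted on reference cross-peaks between protons in fixed intra-residue
geometry, then inverted (r = (k/I)^(1/6)) to convert the conformationally
dependent inter-residue peaks into distances.  Distances are binned into
broad flat-bottom restraints — strong (1.8-2.7 A) and medium (2.8-3.8 A) —
rather than used as exact targets, reflecting the semi-quantitative nature
of intensities at a single mixing time.

In the hexasaccharide the three beta(1->3) linkages (and the two beta(1->4)
linkages) are chemically equivalent for internal residues, so their
cross-peaks overlap; an overlapped peak carries the summed intensity of its
multiplicity (3 or 2) equivalent linkages and is divided back down before
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InputError, MissingPeakError

STRONG_BOUNDS = (1.8, 2.7)
MEDIUM_BOUNDS = (2.8, 3.8)
BIN_SPLIT = 2.75  # midpoint of the 2.7-2.8 A gap between the printed bins
MAX_RESTRAINED = 3.8
DEFAULT_FORCE_CONSTANT = 10.0  # kcal/mol/A^2

#: The eight conformationally dependent inter-residue NOEs of CN6 and their
#: experimental intensity class: for every beta(1->3) linkage a strong
#: H3(GalNAc)-H1(GlcA) and a medium HN(GalNAc)-H1(GlcA) contact, and for
#: every beta(1->4) linkage a strong H1(GalNAc)-H4(GlcA) contact.
CN6_RESTRAINT_PAIRS = (
    ("U2:N1", "beta1-3", "N1:HN", "U2:H1", "medium"),
    ("U2:N1", "beta1-3", "N1:H3", "U2:H1", "strong"),
    ("N3:U2", "beta1-4", "N3:H1", "U2:H4", "strong"),
    ("U4:N3", "beta1-3", "N3:HN", "U4:H1", "medium"),
    ("U4:N3", "beta1-3", "N3:H3", "U4:H1", "strong"),
    ("N5:U4", "beta1-4", "N5:H1", "U4:H4", "strong"),
    ("U6:N5", "beta1-3", "N5:HN", "U6:H1", "medium"),
    ("U6:N5", "beta1-3", "N5:H3", "U6:H1", "strong"),
)

#: Five intra-residue proton pairs in fixed (ring) geometry used to calibrate
#: k: 1,3-diaxial contacts, which do not depend on glycosidic conformation.
CN6_REFERENCE_PAIRS = (
    ("N1:H1", "N1:H3"),
    ("N1:H1", "N1:H5"),
    ("U2:H1", "U2:H3"),
    ("U2:H1", "U2:H5"),
    ("U2:H3", "U2:H5"),
)


@dataclass
class NoePeak:
    atom_a: str  # qualified "U2:H1" identifiers
    atom_b: str
    intensity: float
    overlap_multiplicity: int = 1
    role: str = "conformational"  # or "reference"
    known_distance: Optional[float] = None  # reference pairs only, A

    def __post_init__(self):
        if self.intensity <= 0:
            raise InputError(f"non-positive intensity for {self.atom_a}/{self.atom_b}")
        if self.overlap_multiplicity < 1:
            raise InputError("overlap multiplicity must be >= 1")


@dataclass
class CalibrationModel:
    """I = k * r^-6 spin-pair model; k in intensity * A^6."""

    k: float
    fit_residual: float = 0.0

    def __post_init__(self):
        if self.k <= 0:
            raise InputError("calibration constant k must be positive")


@dataclass
class DistanceRestraint:
    atom_a: str
    atom_b: str
    lower: float
    upper: float
    bin: str
    force_constant: float = DEFAULT_FORCE_CONSTANT
    linkage: str = ""


def fit_calibration(references) -> CalibrationModel:
    """Least-squares fit of k in I = k * r^-6 (zero intercept).

    `references` is a sequence of (intensity, known_distance_A) pairs.  The
    regression is of I against x = r^-6 through the origin, which is the
    physically meaningful form of the spin-pair model:
    k = sum(x*I) / sum(x^2).
    """
    refs = list(references)
    if not refs:
        raise InputError("at least one reference NOE is required")
    intens = np.array([r[0] for r in refs], dtype=float)
    dists = np.array([r[1] for r in refs], dtype=float)
    if np.any(intens <= 0) or np.any(dists <= 0):
        raise InputError("reference intensities and distances must be positive")
    x = dists ** -6.0
    k = float(np.dot(x, intens) / np.dot(x, x))
    resid = float(np.sum((intens - k * x) ** 2))
    return CalibrationModel(k=k, fit_residual=resid)


def predict_distance(intensity: float, model: CalibrationModel) -> float:
    """Invert the spin-pair model: r = (k / I)^(1/6)."""
    if intensity <= 0:
        raise InputError("intensity must be positive")
    return float((model.k / intensity) ** (1.0 / 6.0))


def normalize_overlapped(peak: NoePeak) -> float:
    """Per-linkage intensity of a (possibly overlapped) peak: I / multiplicity."""
    if peak.overlap_multiplicity < 1:
        raise InputError("overlap multiplicity must be >= 1")
    return peak.intensity / peak.overlap_multiplicity


def back_predict_references(model: CalibrationModel, references) -> pd.DataFrame:
    """QC table: predicted vs known distance for each reference pair.

    `references` holds (intensity, known_distance) pairs or NoePeak objects
    with `known_distance` set.  Small |delta| values validate the single-k
    spin-pair treatment of the dataset.
    """
    rows = []
    for i, ref in enumerate(references):
        if isinstance(ref, NoePeak):
            label = f"{ref.atom_a}/{ref.atom_b}"
            intensity, known = normalize_overlapped(ref), ref.known_distance
        else:
            intensity, known = ref
            label = f"ref{i + 1}"
        pred = predict_distance(intensity, model)
        rows.append(
            dict(pair=label, measured_A=known, predicted_A=pred,
                 abs_delta_A=abs(pred - known) if known is not None else np.nan)
        )
    return pd.DataFrame(rows)


def bin_restraint(r: float, atom_a: str, atom_b: str,
                  force_constant: float = DEFAULT_FORCE_CONSTANT,
                  linkage: str = "") -> Optional[DistanceRestraint]:
    """Convert a calibrated distance into a strong/medium flat-bottom restraint.

    r < 2.75 A -> strong (1.8, 2.7); 2.75 <= r <= 3.8 -> medium (2.8, 3.8);
    beyond 3.8 A no restraint is produced (returns None with a warning).
    """
    if r <= 0:
        raise InputError("distance must be positive")
    if r < BIN_SPLIT:
        lo, hi, name = *STRONG_BOUNDS, "strong"
    elif r <= MAX_RESTRAINED:
        lo, hi, name = *MEDIUM_BOUNDS, "medium"
    else:
        import warnings

        warnings.warn(
            f"distance {r:.2f} A for {atom_a}/{atom_b} beyond the medium bin; "
            "no restraint emitted", stacklevel=2,
        )
        return None
    return DistanceRestraint(atom_a, atom_b, lo, hi, name, force_constant, linkage)


def build_restraint_set(peaks, model: CalibrationModel,
                        force_constant: float = DEFAULT_FORCE_CONSTANT):
    """The eight CN6 conformationally dependent restraints from a peak table.

    Each expected pair (CN6_RESTRAINT_PAIRS) must be present among the
    conformational peaks; overlapped peaks are normalised by multiplicity
    before the calibrated distance is computed and binned.
    """
    index = {}
    for p in peaks:
        if p.role != "conformational":
            continue
        index[frozenset((p.atom_a, p.atom_b))] = p
    restraints = []
    for linkage, ltype, a, b, _expected in CN6_RESTRAINT_PAIRS:
        key = frozenset((a, b))
        if key not in index:
            raise MissingPeakError(f"expected NOE peak {linkage} {a}/{b} not found")
        peak = index[key]
        r = predict_distance(normalize_overlapped(peak), model)
        restraint = bin_restraint(r, a, b, force_constant, linkage)
        if restraint is not None:
            restraints.append(restraint)
    return restraints


# ---------------------------------------------------------------------------
# table I/O (TSV with one header row)

PEAK_COLUMNS = ["res_a", "atom_a", "res_b", "atom_b", "intensity", "multiplicity", "role"]


def peaks_to_frame(peaks) -> pd.DataFrame:
    rows = []
    for p in peaks:
        ra, na = p.atom_a.split(":")
        rb, nb = p.atom_b.split(":")
        rows.append(dict(res_a=ra, atom_a=na, res_b=rb, atom_b=nb,
                         intensity=p.intensity, multiplicity=p.overlap_multiplicity,
                         role=p.role, known_distance=p.known_distance))
    return pd.DataFrame(rows)


def write_peaks(peaks, path):
    peaks_to_frame(peaks).to_csv(path, sep="\t", index=False)


def read_peaks(path):
    df = pd.read_csv(path, sep="\t")
    peaks = []
    for _, row in df.iterrows():
        kd = row.get("known_distance")
        peaks.append(
            NoePeak(
                atom_a=f"{row.res_a}:{row.atom_a}",
                atom_b=f"{row.res_b}:{row.atom_b}",
                intensity=float(row.intensity),
                overlap_multiplicity=int(row.multiplicity),
                role=str(row.role),
                known_distance=None if kd is None or pd.isna(kd) else float(kd),
            )
        )
    return peaks


def write_restraints(restraints, path):
    pd.DataFrame(
        [
            dict(atom_a=r.atom_a, atom_b=r.atom_b, lower_A=r.lower, upper_A=r.upper,
                 bin=r.bin, force_constant_kcal_mol_A2=r.force_constant,
                 linkage=r.linkage)
            for r in restraints
        ]
    ).to_csv(path, sep="\t", index=False)


def read_restraints(path):
    df = pd.read_csv(path, sep="\t")
    return [
        DistanceRestraint(row.atom_a, row.atom_b, float(row.lower_A), float(row.upper_A),
                          str(row.bin), float(row.force_constant_kcal_mol_A2),
                          str(row.linkage) if "linkage" in df.columns else "")
        for _, row in df.iterrows()
    ]
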