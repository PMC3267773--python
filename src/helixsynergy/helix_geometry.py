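"""Idealized linear B-DNA geometry of transcription-factor binding sites.

A straight B-DNA helix places every base pair at a fixed azimuthal angle
around the helix axis: moving one base pair along the sequence advances
the azimuth by the helical twist (36 degrees per bp for a 10.0 bp/turn
helix) and the position along the axis by the helical rise (3.4 angstrom).
Two proteins bound at different positions therefore sit at a relative
angular phase determined purely by their center-to-center distance in
base pairs.  This module maps binding-site coordinates to azimuths,
folds pairwise azimuth differences into [0, 180] degrees, and classifies
site pairs as bound on the *same* or *opposite* face of the double helix.

The model deliberately ignores sequence-dependent twist/roll/bend and
protein-induced bending; GAL4- and ZEBRA-class factors bind without
detectably bending their sites, so a rigid straight helix is the
appropriate zeroth-order geometry for promoter design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .exceptions import ConfigError, InputError

__all__ = [
    "HelixParameters",
    "BindingSite",
    "SiteArrangement",
    "Face",
    "FaceClass",
    "AxisModel",
    "ArrangementClassification",
    "azimuth_of",
    "center_to_center",
    "pairwise_phase",
    "fold_angle",
    "classify_pair",
    "classify_arrangement",
    "predict_opposite_spacers",
    "build_axis_model",
    "DEFAULT_TWIST_PER_BP",
    "DEFAULT_RISE_PER_BP",
    "DEFAULT_FACE_BOUNDARY",
    "DEFAULT_EVEN_TOLERANCE",
    "GAL4_SITE_LENGTH",
    "ZIIIB_SITE_LENGTH",
    "TATA_SITE_LENGTH",
]

#: Default helical twist, degrees per base pair (10.0 bp per turn).
DEFAULT_TWIST_PER_BP = 36.0
#: Default helical rise, angstrom per base pair (textbook B-DNA).
DEFAULT_RISE_PER_BP = 3.4
#: Folded-phase threshold separating same-face from opposite-face pairs.
DEFAULT_FACE_BOUNDARY = 90.0
#: Tolerance on circular azimuth gaps when testing for even spacing.
#: With integer center-to-center distances at 36 deg/bp, achievable gaps
#: are multiples of 36 deg, so the best 3-site approximation to 120 deg
#: spacing has gaps {108, 108, 144}; 25 deg admits such designs.
DEFAULT_EVEN_TOLERANCE = 25.0

#: Length of the palindromic GAL4 upstream-activating sequence, bp.
GAL4_SITE_LENGTH = 17
#: Length of the ZIIIB element bound by ZEBRA, bp.
ZIIIB_SITE_LENGTH = 7
#: Length assumed for the TATA box, bp.
TATA_SITE_LENGTH = 8


@dataclass(frozen=True)
class HelixParameters:
    """Geometry of an idealized straight B-DNA helix.

    Parameters
    ----------
    twist_per_bp : float
        Helical twist in degrees per base pair; must lie in (0, 360).
        360 / ``twist_per_bp`` is the helical repeat in bp per turn.
    rise_per_bp : float
        Helical rise in angstrom per base pair; must be positive.
    reference_azimuth : float
        Azimuth in degrees assigned to sequence position 0.
    """

    twist_per_bp: float = DEFAULT_TWIST_PER_BP
    rise_per_bp: float = DEFAULT_RISE_PER_BP
    reference_azimuth: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.twist_per_bp < 360.0):
            raise InputError(
                f"twist_per_bp must be in (0, 360), got {self.twist_per_bp}"
            )
        if not (self.rise_per_bp > 0.0):
            raise InputError(f"rise_per_bp must be > 0, got {self.rise_per_bp}")
        if not np.isfinite(self.reference_azimuth):
            raise InputError("reference_azimuth must be finite")

    @property
    def helical_repeat(self) -> float:
        """Base pairs per full turn (360 / twist)."""
        return 360.0 / self.twist_per_bp


@dataclass(frozen=True)
class BindingSite:
    """A protein binding site on the sense strand, 1-based and inclusive."""

    name: str
    start: int
    length: int
    factor: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise InputError(f"site {self.name!r}: start must be >= 1")
        if self.length < 1:
            raise InputError(f"site {self.name!r}: length must be >= 1")

    @property
    def end(self) -> int:
        """Last occupied position (inclusive)."""
        return self.start + self.length - 1

    @property
    def center(self) -> float:
        """Geometric center in bp; half-integer for even lengths."""
        return self.start + (self.length - 1) / 2.0

    def overlaps(self, other: "BindingSite") -> bool:
        return self.start <= other.end and other.start <= self.end


class Face(str, Enum):
    """Which face of the double helix two factors share."""

    SAME = "same"
    OPPOSITE = "opposite"


@dataclass(frozen=True)
class FaceClass:
    """A same/opposite call together with the boundary used to make it."""

    value: Face
    boundary: float = DEFAULT_FACE_BOUNDARY


def azimuth_of(position_bp: float, params: HelixParameters) -> float:
    """Azimuth of a (possibly half-integer) bp position, in [0, 360).

    The azimuth advances linearly with position:
    ``(reference_azimuth + position * twist) mod 360``.
    """
    if not np.isfinite(position_bp):
        raise InputError(f"position must be finite, got {position_bp}")
    return float(
        np.mod(params.reference_azimuth + position_bp * params.twist_per_bp, 360.0)
    )


def center_to_center(spacer_bp: float, len_a: int, len_b: int) -> float:
    """Convert an edge-to-edge spacer into a center-to-center distance.

    A spacer of ``s`` bp between the inner edges of two sites of lengths
    ``len_a`` and ``len_b`` puts their centers ``s + (len_a + len_b)/2``
    bp apart.  Two 17-bp GAL4 sites separated by a 4-bp spacer are thus
    21 bp center-to-center.
    """
    if spacer_bp < 0:
        raise InputError(f"spacer must be >= 0, got {spacer_bp}")
    if len_a < 1 or len_b < 1:
        raise InputError("site lengths must be >= 1")
    return spacer_bp + (len_a + len_b) / 2.0


def fold_angle(delta_deg: float) -> float:
    """Fold an angular separation into [0, 180] degrees."""
    d = float(np.mod(delta_deg, 360.0))
    return min(d, 360.0 - d)


def pairwise_phase(
    site_a: BindingSite, site_b: BindingSite, params: HelixParameters
) -> float:
    """Folded angular separation of two site centers, degrees in [0, 180].

    Symmetric in its arguments and invariant under translation of both
    sites.  Overlapping sites are phased anyway (useful when exploring
    designs) but provoke a warning.
    """
    if site_a.overlaps(site_b):
        warnings.warn(
            f"sites {site_a.name!r} and {site_b.name!r} overlap; "
            "phasing their centers regardless",
            stacklevel=2,
        )
    delta = azimuth_of(site_a.center, params) - azimuth_of(site_b.center, params)
    return fold_angle(delta)


def classify_pair(
    phase_folded: float, boundary: float = DEFAULT_FACE_BOUNDARY
) -> FaceClass:
    """Classify a folded phase as same-face or opposite-face.

    Phases strictly below ``boundary`` are *same*, strictly above are
    *opposite*; a phase exactly at the boundary is assigned *same*
    (documented tie rule).
    """
    if not (0.0 < boundary < 180.0):
        raise ConfigError(f"boundary must lie in (0, 180), got {boundary}")
    if not (0.0 <= phase_folded <= 180.0):
        raise InputError(f"folded phase must be in [0, 180], got {phase_folded}")
    face = Face.SAME if phase_folded <= boundary else Face.OPPOSITE
    return FaceClass(value=face, boundary=boundary)


@dataclass(frozen=True)
class SiteArrangement:
    """An ordered set of binding sites on one idealized helix.

    Azimuths and the symmetric folded-phase matrix are derived from the
    sites and helix parameters at construction time.
    """

    sites: tuple[BindingSite, ...]
    params: HelixParameters = field(default_factory=HelixParameters)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        if len(self.sites) == 0:
            raise InputError("arrangement needs at least one site")

    @property
    def azimuths(self) -> np.ndarray:
        """Azimuth of each site center, degrees in [0, 360)."""
        return np.array([azimuth_of(s.center, self.params) for s in self.sites])

    @property
    def pairwise_phase_matrix(self) -> np.ndarray:
        """Symmetric matrix of folded phases between site centers."""
        az = self.azimuths
        delta = np.abs(az[:, None] - az[None, :]) % 360.0
        return np.minimum(delta, 360.0 - delta)

    def phase_between(self, i: int, j: int) -> float:
        return float(self.pairwise_phase_matrix[i, j])

    def distance_between(self, i: int, j: int) -> float:
        """Center-to-center distance between sites i and j, bp."""
        return abs(self.sites[i].center - self.sites[j].center)


@dataclass(frozen=True)
class ArrangementClassification:
    """Output of :func:`classify_arrangement`."""

    azimuths: np.ndarray
    pair_classes: dict[tuple[int, int], FaceClass]
    even: bool


def classify_arrangement(
    arrangement: SiteArrangement,
    boundary: float = DEFAULT_FACE_BOUNDARY,
    even_tolerance: float = DEFAULT_EVEN_TOLERANCE,
) -> ArrangementClassification:
    """Classify every site pair and test for even circular spacing.

    The arrangement of k sites is *evenly spaced* iff, after sorting the
    site azimuths around the circle, every gap between circularly
    consecutive azimuths is within ``even_tolerance`` degrees of 360/k.
    """
    n = len(arrangement.sites)
    if n < 2:
        raise InputError("classification needs at least 2 sites")
    phases = arrangement.pairwise_phase_matrix
    pair_classes = {
        (i, j): classify_pair(float(phases[i, j]), boundary)
        for i in range(n)
        for j in range(i + 1, n)
    }
    az = np.sort(arrangement.azimuths)
    gaps = np.diff(np.concatenate([az, [az[0] + 360.0]]))
    even = bool(np.all(np.abs(gaps - 360.0 / n) <= even_tolerance))
    return ArrangementClassification(
        azimuths=arrangement.azimuths, pair_classes=pair_classes, even=even
    )


def predict_opposite_spacers(
    spacer_min: int,
    spacer_max: int,
    step: int,
    site_len: int = GAL4_SITE_LENGTH,
    params: HelixParameters | None = None,
    boundary: float = DEFAULT_FACE_BOUNDARY,
) -> list[int]:
    """Spacers on a grid at which two equal-length sites are opposite-face.

    Evaluates the folded phase of the center-to-center distance
    ``spacer + site_len`` at every grid point and returns the spacers
    whose phase exceeds ``boundary``.  With default geometry (36 deg/bp,
    17-bp sites) the 0-48 bp grid yields {8, 18, 28, 38}, the spacings
    at which both activators project to opposite sides of the helix.
    """
    if step <= 0:
        raise InputError("step must be positive")
    spacers = list(range(spacer_min, spacer_max + 1, step))
    if not spacers:
        raise InputError("empty spacer grid")
    params = params or HelixParameters()
    out = []
    for s in spacers:
        d = center_to_center(s, site_len, site_len)
        phase = fold_angle(d * params.twist_per_bp)
        if classify_pair(phase, boundary).value is Face.OPPOSITE:
            out.append(s)
    return out


@dataclass(frozen=True)
class AxisModel:
    """Per-bp axis points and groove-direction unit vectors.

    ``axis_points[i] = (0, 0, rise * i)``; ``groove_vectors[i]`` is the
    unit vector in the xy-plane at the azimuth of position ``i``.
    """

    axis_points: np.ndarray
    groove_vectors: np.ndarray
    params: HelixParameters


def build_axis_model(n_bp: int, params: HelixParameters | None = None) -> AxisModel:
    """Build an idealized straight-helix coordinate frame of ``n_bp`` steps.

    Consecutive groove vectors are rotated by exactly ``twist_per_bp``
    about the z axis; axis points ascend by ``rise_per_bp`` angstrom.
    """
    if n_bp < 1:
        raise InputError(f"n_bp must be >= 1, got {n_bp}")
    params = params or HelixParameters()
    idx = np.arange(n_bp)
    axis = np.column_stack(
        [np.zeros(n_bp), np.zeros(n_bp), idx * params.rise_per_bp]
    )
    theta = np.deg2rad(params.reference_azimuth + idx * params.twist_per_bp)
    grooves = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n_bp)])
    return AxisModel(axis_points=axis, groove_vectors=grooves, params=params)
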