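"""Seeded synthetic datasets with the statistical structure of the assays.

Every input the analysis pipeline consumes can be generated here:

* replicate dual-luciferase tables — expected activities from the
  equilibrium simulator, multiplied by lognormal measurement noise on
  both the firefly and the Renilla channel (triplicates by default);
* gel tables — free-probe log-migration decreasing linearly with probe
  length, complex lanes additionally retarded in proportion to the
  complex's transverse extent (the analytic two-cluster formula), plus
  Gaussian log-scale noise;
* toy PDB fixtures — DNA axis pseudo-atoms plus one atom cluster per
  bound factor at its site's azimuth, for exercising the structural
  superposition tools without crystallographic input;
* template FASTA sequences with a sidecar table of site coordinates.

A single integer seed makes every generator byte-reproducible; each
generator draws from its own deterministic substream so adding one
output never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activity_analysis import ActivityTable
from .emsa_analysis import GelTable
from .exceptions import ConfigError, InputError
from .helix_geometry import HelixParameters, SiteArrangement, fold_angle
from .simulator import (
    DEFAULT_MODEL_PARAMS,
    SynergyModelParams,
    simulate_template,
)
from .templates import (
    FACTOR_SITE_LENGTHS,
    TATA_FACTOR,
    TemplateDesign,
    two_site_template,
)

__all__ = [
    "NoiseSpec",
    "GelParams",
    "DEFAULT_MOTIFS",
    "generate_activity_dataset",
    "generate_gel_dataset",
    "transverse_extent_analytic",
    "generate_fixture_pdb",
    "generate_template_sequences",
]

# deterministic substream tags
_ACTIVITY_STREAM = 1
_GEL_STREAM = 2


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative lognormal measurement noise for reporter assays.

    ``cv`` is the coefficient of variation of each luminescence channel;
    the firefly/Renilla ratio then has CV ~= cv * sqrt(2).  Three
    parallel replicates per condition by default.
    """

    cv: float = 0.10
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise InputError("cv must be >= 0")
        if self.n_replicates < 1:
            raise InputError("n_replicates must be >= 1")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal multipliers with the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


#: Renilla control luminescence at noise-free baseline, arbitrary counts.
RENILLA_SCALE = 1.0e4


def generate_activity_dataset(
    designs: list[TemplateDesign] | None = None,
    spacers=None,
    factor: str = "GAL4",
    tata_offset: int = 22,
    params: SynergyModelParams | None = None,
    helix: HelixParameters | None = None,
    noise: NoiseSpec | None = None,
    doses=None,
) -> ActivityTable:
    """Replicate luciferase table for template designs or a spacer grid.

    Provide either ``designs`` (explicit templates) or ``spacers`` (a
    two-site spacer series of ``factor``).  With ``doses``, every
    template is simulated at each activator dose (titration layout).
    Firefly counts are the simulator's expected activity times the
    Renilla scale times lognormal noise; Renilla counts are the scale
    times independent lognormal noise, so the per-replicate normalized
    activity equals the noise-free expectation exactly at cv = 0.
    """
    if (designs is None) == (spacers is None):
        raise InputError("provide exactly one of designs or spacers")
    if spacers is not None:
        spacers = [int(s) for s in spacers]
        designs = [
            two_site_template(s, factor=factor, tata_offset=tata_offset)
            for s in spacers
        ]
        spacer_of = {d.name: s for d, s in zip(designs, spacers)}
    else:
        spacer_of = {
            d.name: (d.spacers[1] if d.n_activator_sites == 2 else None)
            for d in designs
        }
    noise = noise or NoiseSpec()
    params = params or DEFAULT_MODEL_PARAMS
    rng = np.random.default_rng(np.random.SeedSequence([noise.seed, _ACTIVITY_STREAM]))
    dose_list = [1.0] if doses is None else [float(d) for d in doses]

    rows = []
    for design in designs:
        for dose in dose_list:
            expected = simulate_template(design, params, helix, dose=dose)
            ff = expected * RENILLA_SCALE * _lognormal_factors(
                rng, noise.cv, noise.n_replicates
            )
            rn = RENILLA_SCALE * _lognormal_factors(rng, noise.cv, noise.n_replicates)
            for rep in range(noise.n_replicates):
                row = {
                    "template_id": design.name,
                    "replicate": rep + 1,
                    "firefly": ff[rep],
                    "renilla": rn[rep],
                }
                if spacer_of.get(design.name) is not None:
                    row["spacer_bp"] = spacer_of[design.name]
                if doses is not None:
                    row["dose"] = dose
                rows.append(row)
    df = pd.DataFrame(rows)
    front = [c for c in ("template_id", "spacer_bp", "dose") if c in df.columns]
    df = df[front + ["replicate", "firefly", "renilla"]]
    return ActivityTable(rows=df)


@dataclass(frozen=True)
class GelParams:
    """Parameters of the synthetic native-gel mobility model.

    log(free migration) = ``log_intercept - length_slope * length``;
    the saturated complex is further retarded by ``extent_coeff`` per
    angstrom of transverse extent, computed from two factor clusters of
    ``cluster_radius`` angstrom at ``radial_distance`` angstrom from
    the helix axis.  ``probe_flank`` is the constant part of the probe
    outside the two sites and their spacer.
    """

    log_intercept: float = 5.0
    length_slope: float = 0.004
    extent_coeff: float = 0.002
    radial_distance: float = 30.0
    cluster_radius: float = 15.0
    probe_flank: int = 80

    def __post_init__(self) -> None:
        if self.length_slope < 0 or self.extent_coeff < 0:
            raise InputError("slopes must be >= 0")


def transverse_extent_analytic(
    phase_deg: float, radial_distance: float, cluster_radius: float
) -> float:
    """Transverse extent of two spherical factor clusters on a helix.

    Projected onto the plane perpendicular to the helix axis, two
    clusters of radius ``rho`` centered ``R`` from the axis and
    separated by azimuth ``phi`` span ``2 rho + 2 R sin(phi / 2)`` —
    minimal when coplanar (same face), maximal when antipodal
    (opposite faces).
    """
    return float(
        2.0 * cluster_radius
        + 2.0 * radial_distance * np.sin(np.deg2rad(fold_angle(phase_deg)) / 2.0)
    )


def generate_gel_dataset(
    spacers,
    factor: str = "GAL4",
    helix: HelixParameters | None = None,
    gel: GelParams | None = None,
    noise_sd: float = 0.005,
    seed: int = 0,
    site_len: int | None = None,
) -> GelTable:
    """Synthetic gel table for a two-site spacer series.

    One lane per spacer; the probe grows with the spacer, free-probe
    migration follows the marker line exactly (plus noise), and the
    complex lane is retarded by the phase-dependent transverse extent.
    With ``noise_sd = 0`` the detrended minima of the output sit
    exactly on the opposite-face spacers.
    """
    spacers = [int(s) for s in spacers]
    if not spacers:
        raise InputError("empty spacer grid")
    helix = helix or HelixParameters()
    gel = gel or GelParams()
    length = site_len if site_len is not None else FACTOR_SITE_LENGTHS[factor]
    rng = np.random.default_rng(np.random.SeedSequence([seed, _GEL_STREAM]))
    rows = []
    for s in spacers:
        probe_len = gel.probe_flank + 2 * length + s
        phase = fold_angle((s + length) * helix.twist_per_bp)
        extent = transverse_extent_analytic(
            phase, gel.radial_distance, gel.cluster_radius
        )
        log_free = gel.log_intercept - gel.length_slope * probe_len
        log_complex = log_free - gel.extent_coeff * extent
        if noise_sd > 0:
            log_free = log_free + rng.normal(0.0, noise_sd)
            log_complex = log_complex + rng.normal(0.0, noise_sd)
        rows.append(
            {
                "spacer_bp": s,
                "probe_length_bp": probe_len,
                "migration_free": float(np.exp(log_free)),
                "migration_complex": float(np.exp(log_complex)),
            }
        )
    return GelTable(lanes=pd.DataFrame(rows))


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """n near-uniform points on a sphere surface (deterministic)."""
    k = np.arange(n, dtype=float)
    phi = np.arccos(1.0 - 2.0 * (k + 0.5) / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return radius * np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def generate_fixture_pdb(
    arrangement: SiteArrangement,
    radial_distance: float = 30.0,
    sphere_radius: float = 15.0,
    atoms_per_factor: int = 32,
) -> str:
    """Toy PDB of an arrangement: axis pseudo-atoms plus factor clusters.

    The DNA is one pseudo-atom per base pair on the helix axis (chain
    A, atom P).  Each site's factor becomes a deterministic spherical
    shell of ``atoms_per_factor`` CA pseudo-atoms of radius
    ``sphere_radius`` centered at ``(R cos(theta), R sin(theta), z)``
    for site azimuth ``theta`` and axial center ``z``.  The text parses
    through :mod:`helixsynergy.structure_model` unchanged.
    """
    from . import structure_model as sm

    params = arrangement.params
    n_bp = max(s.end for s in arrangement.sites) + 1
    chains = [
        sm.make_structure(
            coords=np.column_stack(
                [np.zeros(n_bp), np.zeros(n_bp), np.arange(n_bp) * params.rise_per_bp]
            ),
            chain_id="A",
            atom_name="P",
            res_name="DA",
            element="P",
        )
    ]
    chain_ids = "BCDEFGHIJKLMNOPQRSTUVWXYZ"
    shell = _fibonacci_sphere(atoms_per_factor, sphere_radius)
    azimuths = arrangement.azimuths
    for k, site in enumerate(arrangement.sites):
        theta = np.deg2rad(azimuths[k])
        center = np.array(
            [
                radial_distance * np.cos(theta),
                radial_distance * np.sin(theta),
                site.center * params.rise_per_bp,
            ]
        )
        chains.append(
            sm.make_structure(
                coords=shell + center,
                chain_id=chain_ids[k % len(chain_ids)],
                atom_name="CA",
                res_name="ALA",
                element="C",
            )
        )
    return sm.write_pdb(sm.concatenate(chains))


#: Default binding-motif sequences used when assembling template FASTA.
DEFAULT_MOTIFS: dict[str, str] = {
    "GAL4": "CGGAGGACTGTCCTCCG",  # 17-bp palindromic UAS
    "ZIIIB": "TTAGCAA",  # 7-bp ZIIIB element
    TATA_FACTOR: "TATATATA",  # 8-bp TATA box
}

#: Fixed neutral spacer filler; repeated/truncated to the needed length.
FILLER = "ACTGGTCAACTGGTCAACTGGTCAACTGGTCAACTGGTCAACTGGTCA"


def _filler(n: int) -> str:
    reps = (n // len(FILLER)) + 1
    return (FILLER * reps)[:n]


def generate_template_sequences(
    designs: list[TemplateDesign],
    motifs: dict[str, str] | None = None,
    flank: int = 12,
) -> tuple[str, pd.DataFrame]:
    """Assemble FASTA records and a 1-based site-coordinate table.

    Each design becomes one record: 5' flank, the activator motifs with
    filler spacers, filler to the TATA box, the TATA motif, 3' flank.
    Returns ``(fasta_text, coords)`` where ``coords`` has columns
    template, site, factor, start, end (1-based inclusive).
    """
    motifs = {**DEFAULT_MOTIFS, **(motifs or {})}
    records = []
    coord_rows = []
    for design in designs:
        for f in design.factors:
            if f not in motifs:
                raise ConfigError(f"no motif defined for factor {f!r}")
        seq_parts = [_filler(flank)]
        pos = flank + 1
        for i, (f, gap, length) in enumerate(
            zip(design.factors, design.spacers, design.site_lengths)
        ):
            motif = motifs[f]
            if len(motif) != length:
                raise ConfigError(
                    f"motif for {f!r} is {len(motif)} bp, site expects {length}"
                )
            seq_parts.append(_filler(gap))
            pos += gap
            seq_parts.append(motif)
            coord_rows.append(
                {
                    "template": design.name,
                    "site": f"{f}_{i + 1}",
                    "factor": f,
                    "start": pos,
                    "end": pos + length - 1,
                }
            )
            pos += length
        seq_parts.append(_filler(design.tata_offset))
        pos += design.tata_offset
        tata = motifs[TATA_FACTOR]
        seq_parts.append(tata)
        coord_rows.append(
            {
                "template": design.name,
                "site": "TATA",
                "factor": TATA_FACTOR,
                "start": pos,
                "end": pos + len(tata) - 1,
            }
        )
        seq_parts.append(_filler(flank))
        records.append((design.name, "".join(seq_parts)))
    fasta = "".join(
        f">{name}\n" + "\n".join(seq[i : i + 60] for i in range(0, len(seq), 60)) + "\n"
        for name, seq in records
    )
    return fasta, pd.DataFrame(coord_rows)
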