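"""Promoter template designs: ordered activator sites upstream of a TATA box.

A template is described by the factor bound at each site, the
edge-to-edge spacers between consecutive sites, and the edge-to-edge
offset from the most promoter-proximal activator site to the TATA box.
``build_arrangement`` lays the sites out on a common coordinate axis
(1-based, upstream-to-downstream) so the geometry module can phase them.

The catalog reproduces the site arrangements of the engineered
adenovirus-E4 reporter series: the two-GAL4-site spacer series, the
TATA-offset pairs 142/145 (21 vs 27 bp center-to-center, 22 bp to TATA)
and 193/196 (same spacings, 26 bp to TATA), the three-site designs
190/191/192, the four-site designs 187/189, and the two-ZIIIB ZEBRA
templates Z4Z/Z8Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import InputError
from .helix_geometry import (
    GAL4_SITE_LENGTH,
    TATA_SITE_LENGTH,
    ZIIIB_SITE_LENGTH,
    BindingSite,
    HelixParameters,
    SiteArrangement,
)

__all__ = [
    "TemplateDesign",
    "build_arrangement",
    "two_site_template",
    "single_site_template",
    "TEMPLATE_CATALOG",
    "TATA_FACTOR",
    "DEFAULT_TATA_OFFSET",
    "FACTOR_SITE_LENGTHS",
]

#: Factor label treated as the fixed pre-initiation complex.
TATA_FACTOR = "TATA"
#: Default edge-to-edge distance from proximal activator site to TATA box, bp.
DEFAULT_TATA_OFFSET = 22

FACTOR_SITE_LENGTHS: dict[str, int] = {
    "GAL4": GAL4_SITE_LENGTH,
    "ZIIIB": ZIIIB_SITE_LENGTH,
    TATA_FACTOR: TATA_SITE_LENGTH,
}


@dataclass(frozen=True)
class TemplateDesign:
    """An ordered activator-site layout upstream of a TATA box.

    ``spacers[i]`` is the edge-to-edge gap preceding activator site
    ``i`` (``spacers[0]`` is ignored and must be 0); sites are listed
    distal (upstream) first.  ``tata_offset`` is the edge-to-edge gap
    between the last (proximal) activator site and the TATA box.
    """

    name: str
    factors: tuple[str, ...]
    spacers: tuple[int, ...]
    tata_offset: int = DEFAULT_TATA_OFFSET
    site_lengths: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.factors) < 1:
            raise InputError(f"template {self.name!r}: needs >= 1 activator site")
        if len(self.spacers) != len(self.factors):
            raise InputError(
                f"template {self.name!r}: one spacer per site required "
                "(first entry 0)"
            )
        if self.spacers[0] != 0:
            raise InputError(f"template {self.name!r}: spacers[0] must be 0")
        if any(s < 0 for s in self.spacers):
            raise InputError(f"template {self.name!r}: spacers must be >= 0")
        if self.tata_offset < 0:
            raise InputError(f"template {self.name!r}: tata_offset must be >= 0")
        if not self.site_lengths:
            try:
                lengths = tuple(FACTOR_SITE_LENGTHS[f] for f in self.factors)
            except KeyError as exc:
                raise InputError(
                    f"template {self.name!r}: unknown factor {exc.args[0]!r}; "
                    "provide site_lengths explicitly"
                ) from None
            object.__setattr__(self, "site_lengths", lengths)
        elif len(self.site_lengths) != len(self.factors):
            raise InputError(f"template {self.name!r}: one length per site required")

    @property
    def n_activator_sites(self) -> int:
        return len(self.factors)


def build_arrangement(
    design: TemplateDesign,
    params: HelixParameters | None = None,
    include_tata: bool = True,
) -> SiteArrangement:
    """Lay a design out on a 1-based axis and return its arrangement.

    Sites are placed upstream-to-downstream starting at position 1; the
    TATA box (if included) follows the proximal activator site after
    ``tata_offset`` bp and carries the ``TATA`` factor label.
    """
    params = params or HelixParameters()
    sites: list[BindingSite] = []
    pos = 1
    for i, (factor, gap, length) in enumerate(
        zip(design.factors, design.spacers, design.site_lengths)
    ):
        pos += gap
        sites.append(
            BindingSite(name=f"{factor}_{i + 1}", start=pos, length=length, factor=factor)
        )
        pos += length
    if include_tata:
        pos += design.tata_offset
        sites.append(
            BindingSite(
                name="TATA", start=pos, length=TATA_SITE_LENGTH, factor=TATA_FACTOR
            )
        )
    return SiteArrangement(sites=tuple(sites), params=params)


def two_site_template(
    spacer: int,
    factor: str = "GAL4",
    tata_offset: int = DEFAULT_TATA_OFFSET,
    name: str | None = None,
) -> TemplateDesign:
    """Two identical activator sites separated by an edge-to-edge spacer."""
    return TemplateDesign(
        name=name or f"{factor}x2_s{spacer}",
        factors=(factor, factor),
        spacers=(0, spacer),
        tata_offset=tata_offset,
    )


def single_site_template(
    factor: str = "GAL4",
    tata_offset: int = DEFAULT_TATA_OFFSET,
    name: str | None = None,
) -> TemplateDesign:
    """A single activator site (the G1/Z1 reference templates)."""
    return TemplateDesign(
        name=name or f"{factor}x1",
        factors=(factor,),
        spacers=(0,),
        tata_offset=tata_offset,
    )


def _gal4(name: str, spacers: tuple[int, ...], tata_offset: int) -> TemplateDesign:
    return TemplateDesign(
        name=name,
        factors=tuple("GAL4" for _ in spacers),
        spacers=spacers,
        tata_offset=tata_offset,
    )


#: Catalog of the engineered reporter templates, keyed by template id.
#: Spacers are edge-to-edge; with 17-bp GAL4 sites a 4-bp spacer is
#: 21 bp center-to-center and a 10-bp spacer is 27 bp center-to-center.
TEMPLATE_CATALOG: dict[str, TemplateDesign] = {
    # one GAL4 site, the synergy reference
    "G1": single_site_template("GAL4", tata_offset=22, name="G1"),
    # two sites, 21 vs 27 bp center-to-center, 22 bp to TATA
    "142": _gal4("142", (0, 4), 22),
    "145": _gal4("145", (0, 10), 22),
    # same spacings, 26 bp to TATA
    "193": _gal4("193", (0, 4), 26),
    "196": _gal4("196", (0, 10), 26),
    # three sites: all same face / ~120 deg steps / proximal opposite distal two
    "190": _gal4("190", (0, 3, 3), 22),
    "191": _gal4("191", (0, 6, 6), 22),
    "192": _gal4("192", (0, 3, 8), 22),
    # four sites: all same face / proximal opposite the distal three
    "187": _gal4("187", (0, 3, 3, 3), 22),
    "189": _gal4("189", (0, 3, 3, 8), 22),
    # ZEBRA two-site templates: 4-bp spacer same face, 8-bp spacer opposite
    "Z1": single_site_template("ZIIIB", tata_offset=22, name="Z1"),
    "Z4Z": two_site_template(4, factor="ZIIIB", name="Z4Z"),
    "Z8Z": two_site_template(8, factor="ZIIIB", name="Z8Z"),
}
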