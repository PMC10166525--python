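"""Feature taxonomy for murine echocardiography feature tables.

The left ventricle is divided into six short-axis wall segments; named
regions are unions of those segments, represented downstream by averaged
segmental features.  Speckle-tracking (STE) deformation features follow a
fixed grammar, ``<view>_<phase>_<locale>_<dimension>_<metric>``, where the
locale is a segment name, a region name, or ``Global``.  Conventional
echocardiography features are prefixed ``mmode_`` (M-mode) or ``pwd_``
(pulse-wave Doppler).
"""

from __future__ import annotations

from dataclasses import dataclass, field

SEGMENTS: tuple[str, ...] = (
    "AntSeptum",
    "AntFree",
    "LatWall",
    "PostWall",
    "InfFreeWall",
    "PostSeptal",
)

#: Region -> member segments. Every segment belongs to at least two regions;
#: Septal and Free partition the six segments between them.
REGION_MAP: dict[str, tuple[str, ...]] = {
    "Anterior": ("AntSeptum", "AntFree", "LatWall"),
    "Posterior": ("PostSeptal", "InfFreeWall", "PostWall"),
    "Septal": ("AntSeptum", "PostSeptal"),
    "Free": ("AntFree", "LatWall", "PostWall", "InfFreeWall"),
    "AnteriorFree": ("AntFree", "LatWall"),
    "PosteriorFree": ("InfFreeWall", "PostWall"),
}

VIEWS: tuple[str, ...] = ("short", "long")
PHASES: tuple[str, ...] = ("systolic", "diastolic")
#: Radial deformation is measured in both views; circumferential only in the
#: short axis and longitudinal only in the long axis.
VIEW_DIMENSIONS: dict[str, tuple[str, ...]] = {
    "short": ("radial", "circumferential"),
    "long": ("radial", "longitudinal"),
}
METRICS: tuple[str, ...] = ("velocity", "displacement", "strain", "strain_rate")

#: Conventional M-mode measurements (wall thicknesses, chamber dimensions,
#: volumes and the systolic-function indices EF/FS).
MMODE_BASE_NAMES: tuple[str, ...] = (
    "HR",
    "EF",
    "FS",
    "CO",
    "SV",
    "LV_Mass",
    "LVAW_s",
    "LVAW_d",
    "LVPW_s",
    "LVPW_d",
    "LVED_s",
    "LVED_d",
    "LVEV_s",
    "LVEV_d",
    "MPI",
    "LV_Mass_Cor",
    "Endo_Area_d",
)

#: Pulse-wave Doppler mitral-inflow and timing measurements.
PWD_BASE_NAMES: tuple[str, ...] = (
    "MV_E",
    "MV_A",
    "E_A_Ratio",
    "MV_Decel",
    "MV_Decel_Time",
    "IVRT",
    "IVCT",
    "ET",
    "MV_Vmax",
    "MV_Vmean",
    "MV_VTI",
    "AET",
)

#: Whole-LV trace outputs reported alongside the grammar-based global STE
#: deformation features.
GLOBAL_EXTRA_BASE_NAMES: tuple[str, ...] = ("EF_trace", "FAC", "SV_trace", "CO_trace")

GLOBAL_LOCALE = "Global"

#: Per-segment feature budget used in prevalence accounting: four
#: view/phase orientations times four deformation metrics.
DEFAULT_PREVALENCE_BUDGET = 16


class SchemaError(ValueError):
    """Raised when a feature schema cannot be constructed consistently."""


def ste_feature_names(locale: str) -> list[str]:
    """Grammar-based STE feature names for one locale (segment/region/Global).

    2 views x 2 phases x 2 view-compatible dimensions x 4 metrics = 32 names.
    """
    names = []
    for view in VIEWS:
        for phase in PHASES:
            for dim in VIEW_DIMENSIONS[view]:
                for metric in METRICS:
                    names.append(f"{view}_{phase}_{locale}_{dim}_{metric}")
    return names


def _family_names(prefix: str, base: tuple[str, ...], count: int) -> list[str]:
    """First `count` names from a base list, padded with aux fillers."""
    names = [f"{prefix}_{b}" for b in base[:count]]
    for i in range(len(names), count):
        names.append(f"{prefix}_aux_{i - len(base) + 1}")
    return names


@dataclass(frozen=True)
class FeatureSchema:
    """The full feature taxonomy used by simulation, engineering and scoring.

    Attributes
    ----------
    segments, region_map :
        LV wall segments and the named segment unions.
    mmode_features, pwd_features, global_features :
        Conventional and global-STE feature names.
    segment_features :
        Segment -> its 32 grammar-based STE feature names.
    prevalence_budget_per_segment :
        Feature count attributed to one segment when normalizing regional
        prevalence scores (independent of the generator's per-segment count).
    """

    segments: tuple[str, ...] = SEGMENTS
    region_map: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(REGION_MAP)
    )
    mmode_features: tuple[str, ...] = ()
    pwd_features: tuple[str, ...] = ()
    global_features: tuple[str, ...] = ()
    segment_features: dict[str, tuple[str, ...]] = field(default_factory=dict)
    prevalence_budget_per_segment: int = DEFAULT_PREVALENCE_BUDGET

    def __post_init__(self):
        all_names = list(self.all_features)
        if len(set(all_names)) != len(all_names):
            dupes = sorted({n for n in all_names if all_names.count(n) > 1})
            raise SchemaError(f"duplicate feature names: {dupes}")
        covered = set()
        for region, members in self.region_map.items():
            if len(members) < 1:
                raise SchemaError(f"region {region} has no member segments")
            unknown = set(members) - set(self.segments)
            if unknown:
                raise SchemaError(f"region {region} references unknown segments {unknown}")
            covered.update(members)

    @property
    def all_ste_segment_features(self) -> list[str]:
        """STE features of all segments, in segment order."""
        out: list[str] = []
        for seg in self.segments:
            out.extend(self.segment_features[seg])
        return out

    @property
    def all_features(self) -> list[str]:
        """Every raw (pre-region-derivation) feature, in canonical order."""
        return (
            list(self.mmode_features)
            + list(self.pwd_features)
            + list(self.global_features)
            + self.all_ste_segment_features
        )

    def region_feature_names(self, region: str) -> list[str]:
        """Names of the derived region-average features for one region."""
        if region not in self.region_map:
            raise SchemaError(f"unknown region {region!r}")
        return ste_feature_names(region)

    @property
    def all_region_features(self) -> list[str]:
        out: list[str] = []
        for region in self.region_map:
            out.extend(self.region_feature_names(region))
        return out

    def locale_of(self, feature: str) -> str:
        """Locale tag of a feature name.

        Returns a segment name, region name, ``"Global"``, ``"mmode"`` or
        ``"pwd"``.  Raises :class:`SchemaError` for unparseable names.
        """
        if feature.startswith("mmode_"):
            return "mmode"
        if feature.startswith("pwd_"):
            return "pwd"
        if feature in self._global_set:
            return GLOBAL_LOCALE
        parts = feature.split("_")
        if len(parts) >= 5 and parts[0] in VIEWS and parts[1] in PHASES:
            locale = parts[2]
            if locale in self.segments or locale in self.region_map or locale == GLOBAL_LOCALE:
                return locale
        raise SchemaError(f"cannot attribute feature {feature!r} to a locale")

    @property
    def _global_set(self) -> frozenset:
        return frozenset(self.global_features)

    @property
    def lv_mass_feature(self) -> str:
        return "mmode_LV_Mass"


def build_schema(
    n_mmode: int = 17,
    n_pwd: int = 12,
    n_global: int = 36,
    prevalence_budget_per_segment: int = DEFAULT_PREVALENCE_BUDGET,
) -> FeatureSchema:
    """Construct the default feature schema.

    Parameters set the sizes of the conventional (M-mode, PWD) and global STE
    feature families; the per-segment STE block is fixed by the grammar at 32
    features.  Global STE features are the 32 grammar names plus whole-trace
    fillers (or a truncation if ``n_global`` < 32).
    """
    mmode = tuple(_family_names("mmode", MMODE_BASE_NAMES, n_mmode))
    pwd = tuple(_family_names("pwd", PWD_BASE_NAMES, n_pwd))
    global_grammar = ste_feature_names(GLOBAL_LOCALE)
    if n_global <= len(global_grammar):
        global_feats = tuple(global_grammar[:n_global])
    else:
        extras = _family_names("global", GLOBAL_EXTRA_BASE_NAMES, n_global - len(global_grammar))
        global_feats = tuple(global_grammar + extras)
    seg_feats = {seg: tuple(ste_feature_names(seg)) for seg in SEGMENTS}
    return FeatureSchema(
        mmode_features=mmode,
        pwd_features=pwd,
        global_features=global_feats,
        segment_features=seg_feats,
        prevalence_budget_per_segment=prevalence_budget_per_segment,
    )
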