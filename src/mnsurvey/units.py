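"""SI unit standardization for biomarker concentrations.

Laboratories report micronutrient biomarkers in a mixture of conventional
(mass-per-volume) and SI (molar) units.  Every downstream step in this
package — cutoff classification in particular — assumes a single canonical
SI unit per biomarker, so all columns are converted immediately after
ingestion through a factor-based registry.

Mass→molar factors are derived from molar masses::

    c[umol/L] = c[ug/dL] * 10 / M        (M in g/mol)
    c[pmol/L] = c[pg/mL] * 1000 / M
    c[nmol/L] = c[ng/mL] * 1000 / M

Unknown (biomarker, unit) pairs never pass through silently: validation
fails before any value is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "UnitConversion",
    "ConversionRegistry",
    "CANONICAL_UNITS",
    "MOLAR_MASS_G_PER_MOL",
    "default_registry",
    "normalize_unit",
    "register_conversion",
    "convert_to_si",
]

#: Canonical SI unit per built-in biomarker.
CANONICAL_UNITS: dict[str, str] = {
    "ferritin": "ug/L",
    "stfr": "mg/L",
    "rbp": "umol/L",
    "retinol": "umol/L",
    "zinc": "umol/L",
    "serum_folate": "nmol/L",
    "rbc_folate": "nmol/L",
    "b12": "pmol/L",
    "agp": "g/L",
    "crp": "mg/L",
}

#: Molar masses used to derive the shipped mass→molar factors.
MOLAR_MASS_G_PER_MOL: dict[str, float] = {
    "retinol": 286.45,
    "zinc": 65.38,
    "b12": 1355.37,
    "serum_folate": 441.40,
    "rbc_folate": 441.40,
}


def normalize_unit(unit: str) -> str:
    """Normalize a unit string to a registry key.

    Micro may be written ``u``, ``μ`` (Greek mu), ``µ`` (micro sign) or
    ``mcg``; comparison is case-insensitive and ignores internal spaces.
    """
    u = unit.strip().replace("μ", "u").replace("µ", "u").replace(" ", "")
    u = u.lower().replace("mcg", "ug")
    return u


@dataclass(frozen=True)
class UnitConversion:
    """One multiplicative conversion: ``value_si = value * factor``."""

    biomarker: str
    from_unit: str
    to_unit: str
    factor: float

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValueError(
                f"conversion factor must be > 0, got {self.factor!r} "
                f"for {self.biomarker} {self.from_unit}->{self.to_unit}"
            )


class UnitError(ValueError):
    """Raised for unknown units or conflicting registrations."""


@dataclass
class ConversionRegistry:
    """Lookup table (biomarker, source unit) → factor to the canonical SI unit.

    Every biomarker carries at least the identity entry for its canonical
    unit; user biomarkers must be registered before conversion.
    """

    canonical_units: dict[str, str] = field(default_factory=dict)
    _entries: dict[tuple[str, str], UnitConversion] = field(default_factory=dict)

    def canonical_unit(self, biomarker: str) -> str:
        try:
            return self.canonical_units[biomarker]
        except KeyError:
            raise UnitError(f"no canonical unit registered for biomarker {biomarker!r}")

    def register(self, entry: UnitConversion) -> None:
        """Add an entry; identical re-registration is a no-op, conflicts raise."""
        bm = entry.biomarker
        if bm not in self.canonical_units:
            self.canonical_units[bm] = entry.to_unit
            ident = UnitConversion(bm, entry.to_unit, entry.to_unit, 1.0)
            self._entries[(bm, normalize_unit(entry.to_unit))] = ident
        canon = self.canonical_units[bm]
        if normalize_unit(entry.to_unit) != normalize_unit(canon):
            raise UnitError(
                f"{bm}: target unit {entry.to_unit!r} differs from canonical {canon!r}"
            )
        key = (bm, normalize_unit(entry.from_unit))
        existing = self._entries.get(key)
        if existing is not None and existing.factor != entry.factor:
            raise UnitError(
                f"{bm} {entry.from_unit!r}: conflicting factors "
                f"{existing.factor!r} (registered) vs {entry.factor!r} (new)"
            )
        self._entries[key] = replace(entry, from_unit=normalize_unit(entry.from_unit))

    def factor(self, biomarker: str, from_unit: str) -> float:
        key = (biomarker, normalize_unit(from_unit))
        try:
            return self._entries[key].factor
        except KeyError:
            known = sorted(u for b, u in self._entries if b == biomarker)
            raise UnitError(
                f"no conversion for biomarker {biomarker!r} from unit {from_unit!r}; "
                f"known source units: {known or 'none'}"
            )

    def knows(self, biomarker: str, from_unit: str) -> bool:
        return (biomarker, normalize_unit(from_unit)) in self._entries

    def entries(self) -> list[UnitConversion]:
        return sorted(self._entries.values(), key=lambda e: (e.biomarker, e.from_unit))

    def copy(self) -> "ConversionRegistry":
        return ConversionRegistry(dict(self.canonical_units), dict(self._entries))


def default_registry() -> ConversionRegistry:
    """Registry shipped with the package.

    Identity entries for every canonical unit, plus the common conventional
    units.  sTfR assays are not mutually calibrated, so no molar conversion
    is shipped for sTfR: users who need nmol/L must register their
    assay-specific factor explicitly.
    """
    reg = ConversionRegistry()
    for bm, unit in CANONICAL_UNITS.items():
        reg.register(UnitConversion(bm, unit, unit, 1.0))

    m = MOLAR_MASS_G_PER_MOL
    extra = [
        # ng/mL ≡ ug/L (both are 1e-9 g / 1e-3 L)
        UnitConversion("ferritin", "ng/mL", "ug/L", 1.0),
        UnitConversion("ferritin", "ug/dL", "ug/L", 10.0),
        UnitConversion("retinol", "ug/dL", "umol/L", 10.0 / m["retinol"]),
        UnitConversion("rbp", "ug/dL", "umol/L", 10.0 / 21000.0),  # RBP4 ~21 kDa
        UnitConversion("rbp", "mg/L", "umol/L", 1000.0 / 21000.0),
        UnitConversion("zinc", "ug/dL", "umol/L", 10.0 / m["zinc"]),
        UnitConversion("zinc", "mg/L", "umol/L", 1000.0 / m["zinc"]),
        UnitConversion("b12", "pg/mL", "pmol/L", 1000.0 / m["b12"]),
        UnitConversion("b12", "ng/L", "pmol/L", 1000.0 / m["b12"]),
        UnitConversion("serum_folate", "ng/mL", "nmol/L", 1000.0 / m["serum_folate"]),
        UnitConversion("serum_folate", "ug/L", "nmol/L", 1000.0 / m["serum_folate"]),
        UnitConversion("rbc_folate", "ng/mL", "nmol/L", 1000.0 / m["rbc_folate"]),
        UnitConversion("crp", "mg/dL", "mg/L", 10.0),
        UnitConversion("crp", "ug/mL", "mg/L", 1.0),
        UnitConversion("agp", "mg/dL", "g/L", 0.01),
        UnitConversion("agp", "mg/L", "g/L", 0.001),
    ]
    for e in extra:
        reg.register(e)
    return reg


def register_conversion(
    registry: ConversionRegistry, entry: UnitConversion
) -> ConversionRegistry:
    """Functional wrapper around :meth:`ConversionRegistry.register`."""
    out = registry.copy()
    out.register(entry)
    return out


def convert_to_si(ds, registry: ConversionRegistry | None = None):
    """Convert every biomarker column of a standardized dataset to SI units.

    Validates all (biomarker, unit) pairs up front so a failure never leaves
    the dataset half-converted.  Missing values stay missing.

    Parameters
    ----------
    ds : mnsurvey.ingest.StandardizedDataset
    registry : ConversionRegistry, optional
        Defaults to the shipped registry.
    """
    if registry is None:
        registry = default_registry()
    problems = [
        (bm, unit)
        for bm, unit in ds.units.items()
        if not registry.knows(bm, unit)
    ]
    if problems:
        desc = ", ".join(f"{bm} [{unit}]" for bm, unit in problems)
        raise UnitError(f"unresolvable unit(s): {desc}")

    out = ds.copy()
    for bm, unit in ds.units.items():
        f = registry.factor(bm, unit)
        if f != 1.0:
            out.data[bm] = out.data[bm] * f
        out.units[bm] = registry.canonical_unit(bm)
    return out
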