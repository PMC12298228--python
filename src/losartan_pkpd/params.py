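"""Model parameters, dosing, and their file formats.

The kinetic model of losartan disposition is parameterized by 13 constants:
the gastric pyloric valve amplitude ``a`` (1/h) and period ``b`` (h); three
transport rate constants around the enterocyte compartment (``k_int_ent``,
``k_ent_int``, ``k_ent_cc``, all 1/h), of which ``k_ent_int`` is the
ABCB1-mediated efflux back into the intestinal lumen; the CYP2C9 conversion
rate ``k_m`` (1/h) and its time delay ``T`` (h); apparent clearances and
distribution volumes of the metabolite E-3174 (``CL_m`` L/h, ``Vm`` L) and of
losartan in the central (``CL_p`` L/h, ``Vp_1`` L) and peripheral
(``Q`` L/h inter-compartment clearance, ``Vp_2`` L) compartments.

An optional first-order intestinal loss ``k_int_ex`` (1/h, default 0) is
provided as a configurable mechanism; the reference topology has no such loss.

Parameter files are flat JSON or YAML key -> value mappings using exactly
these symbol names.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path

import yaml

from .errors import InvalidParameterError

#: Molecular weight of losartan potassium (g/mol); converts mg doses to nmol.
LOSARTAN_POTASSIUM_MW = 461.01

_RATE_FIELDS = ("k_int_ent", "k_ent_int", "k_ent_cc", "k_m", "T", "k_int_ex")
_POSITIVE_FIELDS = ("a", "b", "CL_m", "Vm", "CL_p", "Vp_1", "Vp_2")
_NONNEG_FIELDS = ("Q",)


@dataclass(frozen=True)
class ModelParameters:
    """The kinetic/volume parameters of the five-compartment model.

    All rate constants are first-order (1/h), clearances are L/h and volumes
    are L (apparent, i.e. uncorrected for oral bioavailability).
    """

    a: float
    b: float
    k_int_ent: float
    k_ent_int: float
    k_ent_cc: float
    k_m: float
    T: float
    CL_m: float
    Vm: float
    CL_p: float
    Vp_1: float
    Q: float
    Vp_2: float
    k_int_ex: float = 0.0

    def __post_init__(self) -> None:
        for name in _POSITIVE_FIELDS:
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidParameterError(f"{name} must be strictly positive, got {v!r}")
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise InvalidParameterError(f"{name} must be nonnegative, got {v!r}")
        for name in _NONNEG_FIELDS:
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise InvalidParameterError(f"{name} must be nonnegative, got {v!r}")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise InvalidParameterError(f"unknown parameter keys: {sorted(unknown)}")
        missing = known - set(mapping) - {"k_int_ex"}
        if missing:
            raise InvalidParameterError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix.lower() in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(data, sort_keys=True))
        else:
            path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParameters":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise InvalidParameterError(f"parameter file {path} is not a flat mapping")
        return cls.from_dict(data)

    def replace(self, **updates: float) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **updates)


@dataclass(frozen=True)
class DoseRegimen:
    """A single oral dose of losartan potassium.

    ``dose_mg`` is the labelled dose in mg of the potassium salt;
    ``molecular_weight`` (g/mol) converts it to nmol of drug;
    ``administration_time`` (h) is when the dose enters the stomach.
    """

    dose_mg: float
    molecular_weight: float = LOSARTAN_POTASSIUM_MW
    administration_time: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dose_mg) and self.dose_mg >= 0):
            raise InvalidParameterError(f"dose_mg must be >= 0, got {self.dose_mg!r}")
        if not (math.isfinite(self.molecular_weight) and self.molecular_weight > 0):
            raise InvalidParameterError(
                f"molecular_weight must be > 0, got {self.molecular_weight!r}"
            )
        if not (math.isfinite(self.administration_time) and self.administration_time >= 0):
            raise InvalidParameterError(
                f"administration_time must be >= 0, got {self.administration_time!r}"
            )

    def amount_nmol(self) -> float:
        """Dose in nmol: dose_mg x 1e6 (mg -> ng) / molecular weight."""
        return self.dose_mg * 1.0e6 / self.molecular_weight


def dose_to_amount(dose: DoseRegimen) -> float:
    """Convert an oral dose of losartan potassium to nmol entering the stomach."""
    return dose.amount_nmol()


def default_parameters() -> ModelParameters:
    """Load the package's default (genotype-neutral) parameter set.

    These defaults are a synthetic stand-in: they are not fitted to any
    clinical dataset but calibrated analytically so that single-dose losartan
    and E-3174 exposures after 50 mg fall in the range reported for
    CYP2C9*1/*1 carriers (AUC_losartan ~ 1.35e3 nmol*h/L, AUC_E-3174 ~
    7.7e3 nmol*h/L). Genotype-specific ``k_m`` and ``k_ent_int`` are applied
    on top by :mod:`losartan_pkpd.genotypes`.
    """
    ref = resources.files("losartan_pkpd.data").joinpath("default_parameters_synthetic.json")
    return ModelParameters.from_dict(json.loads(ref.read_text()))
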