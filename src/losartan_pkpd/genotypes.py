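"""Genotype nomenclature parsing and genotype -> rate-constant mapping.

CYP2C9 genotypes are written as two star alleles, e.g. ``CYP2C9*1/CYP2C9*1``.
ABCB1 genotypes are written as nucleotide pairs at the gene's three common
coding SNPs: a 6-letter label like ``CC/GG/CC`` gives the two alleles at
positions 1236, 2677 and 3435 (in that order); a 4-letter label like
``GT/CT`` gives positions 2677 and 3435 only.

The fitted rate constants cover exactly the homozygous genotypes the model
was trained on — ``k_m`` (CYP2C9 conversion of losartan to E-3174) for
*1/*1 and *3/*3, and ``k_ent_int`` (ABCB1 efflux) for GG/CC, GT/CT and
TT/TT. Because the three ABCB1 SNPs are in strong linkage disequilibrium,
the 6-letter haplotypes CC/GG/CC and TT/TT/TT are treated as equivalent to
GG/CC and TT/TT. Anything else (heterozygous CYP2C9, rare ABCB1 diplotypes,
the rare *2 allele) raises :class:`UnsupportedGenotypeError` — there is no
interpolation between fitted genotypes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

from .errors import GenotypeParseError, UnsupportedGenotypeError
from .params import ModelParameters, default_parameters

__all__ = [
    "ParsedGenotype",
    "GenotypeProfile",
    "parse_genotype_label",
    "lookup_rate_constants",
    "genotype_parameters",
    "supported_genotypes",
    "rate_constant_table",
]

_NUCLEOTIDES = frozenset("ACGT")
_CYP_ALLELE = re.compile(r"^CYP2C9\*(\d+)$")
#: SNP positions addressed by 6- and 4-letter ABCB1 labels, in label order.
_ABCB1_POSITIONS_6 = (1236, 2677, 3435)
_ABCB1_POSITIONS_4 = (2677, 3435)


@dataclass(frozen=True)
class ParsedGenotype:
    """A structured genotype: gene plus per-position alleles.

    For CYP2C9 ``alleles`` holds the two star alleles sorted (canonical
    form); for ABCB1 ``positions`` maps SNP position -> sorted nucleotide
    pair.
    """

    gene: str
    alleles: tuple[str, str] | None = None
    positions: Mapping[int, tuple[str, str]] | None = None

    @property
    def canonical_label(self) -> str:
        if self.gene == "CYP2C9":
            return "/".join(self.alleles)
        pairs = ["".join(self.positions[p]) for p in sorted(self.positions)]
        return "/".join(pairs)


def parse_genotype_label(label: str) -> ParsedGenotype:
    """Parse a CYP2C9 star-allele label or an ABCB1 4/6-letter label."""
    if not isinstance(label, str) or not label.strip():
        raise GenotypeParseError("empty genotype label")
    label = label.strip()

    if "CYP2C9" in label.upper():
        parts = label.split("/")
        if len(parts) != 2:
            raise GenotypeParseError(
                f"CYP2C9 label must be two '/'-separated star alleles: {label!r}"
            )
        alleles = []
        for tok in parts:
            m = _CYP_ALLELE.match(tok.strip())
            if not m:
                raise GenotypeParseError(f"invalid CYP2C9 star allele: {tok!r}")
            alleles.append(tok.strip())
        return ParsedGenotype(gene="CYP2C9", alleles=tuple(sorted(alleles)))

    parts = [tok.strip() for tok in label.split("/")]
    if len(parts) == 3:
        positions = _ABCB1_POSITIONS_6
    elif len(parts) == 2:
        positions = _ABCB1_POSITIONS_4
    else:
        raise GenotypeParseError(
            f"ABCB1 label must be 2 or 3 '/'-separated nucleotide pairs: {label!r}"
        )
    mapping: dict[int, tuple[str, str]] = {}
    for pos, tok in zip(positions, parts):
        if len(tok) != 2:
            raise GenotypeParseError(f"nucleotide pair {tok!r} must be 2 letters")
        if not set(tok) <= _NUCLEOTIDES:
            raise GenotypeParseError(f"invalid nucleotide in token {tok!r}")
        mapping[pos] = tuple(sorted(tok))
    return ParsedGenotype(gene="ABCB1", positions=mapping)


def _constants() -> dict:
    ref = resources.files("losartan_pkpd.data").joinpath("genotype_rate_constants.json")
    return json.loads(ref.read_text())


def rate_constant_table() -> dict:
    """The versioned genotype -> rate-constant table shipped with the package."""
    return _constants()


def supported_genotypes() -> dict[str, list[str]]:
    tbl = _constants()
    return {
        "CYP2C9": sorted(tbl["k_m_per_cyp2c9"]),
        "ABCB1": sorted(tbl["k_ent_int_per_abcb1"]) + sorted(tbl["abcb1_haplotype_aliases"]),
    }


def lookup_rate_constants(genotype: str | ParsedGenotype) -> tuple[str, float]:
    """Map a fitted genotype to its rate constant.

    Returns ``("k_m", value)`` for CYP2C9 genotypes and
    ``("k_ent_int", value)`` for ABCB1 genotypes. 6-letter haplotypes are
    resolved through the linkage-disequilibrium aliases. Unfitted genotypes
    raise :class:`UnsupportedGenotypeError` naming the label.
    """
    original = genotype.strip() if isinstance(genotype, str) else None
    parsed = parse_genotype_label(genotype) if isinstance(genotype, str) else genotype
    tbl = _constants()
    label = parsed.canonical_label
    shown = label if original in (None, label) else f"{original} (canonical {label})"
    if parsed.gene == "CYP2C9":
        try:
            return "k_m", float(tbl["k_m_per_cyp2c9"][label])
        except KeyError:
            raise UnsupportedGenotypeError(
                f"no fitted k_m for CYP2C9 genotype {shown}; fitted genotypes: "
                f"{sorted(tbl['k_m_per_cyp2c9'])}"
            ) from None
    # ABCB1: resolve 6-letter haplotypes to their 4-letter equivalents
    if parsed.positions is not None and len(parsed.positions) == 3:
        alias = tbl["abcb1_haplotype_aliases"].get(label)
        if alias is None:
            raise UnsupportedGenotypeError(
                f"no fitted k_ent_int for ABCB1 haplotype {shown}; supported "
                f"6-letter haplotypes: {sorted(tbl['abcb1_haplotype_aliases'])}"
            )
        label = alias
    try:
        return "k_ent_int", float(tbl["k_ent_int_per_abcb1"][label])
    except KeyError:
        raise UnsupportedGenotypeError(
            f"no fitted k_ent_int for ABCB1 genotype {shown}; fitted genotypes: "
            f"{sorted(tbl['k_ent_int_per_abcb1'])}"
        ) from None


@dataclass(frozen=True)
class GenotypeProfile:
    """A joint CYP2C9 x ABCB1 genotype with its mapped rate constants."""

    cyp2c9_label: str
    abcb1_label: str
    k_m: float
    k_ent_int: float


def genotype_parameters(
    cyp2c9: str = "CYP2C9*1/CYP2C9*1",
    abcb1: str = "GG/CC",
    base: ModelParameters | None = None,
) -> ModelParameters:
    """Model parameters for a joint genotype.

    Applies the fitted ``k_m`` (CYP2C9) and ``k_ent_int`` (ABCB1) on top of
    ``base`` (package defaults if omitted).
    """
    base = base if base is not None else default_parameters()
    name_m, k_m = lookup_rate_constants(cyp2c9)
    name_e, k_ei = lookup_rate_constants(abcb1)
    assert name_m == "k_m" and name_e == "k_ent_int"
    return base.replace(k_m=k_m, k_ent_int=k_ei)


def genotype_profile(cyp2c9: str, abcb1: str) -> GenotypeProfile:
    """Build a :class:`GenotypeProfile` from two labels."""
    _, k_m = lookup_rate_constants(cyp2c9)
    _, k_ei = lookup_rate_constants(abcb1)
    return GenotypeProfile(
        cyp2c9_label=parse_genotype_label(cyp2c9).canonical_label,
        abcb1_label=parse_genotype_label(abcb1).canonical_label,
        k_m=k_m,
        k_ent_int=k_ei,
    )
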