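"""Multi-locus genetics of the SSIMS strain family.

The engineered genotype space is small and discrete: an X-linked female-lethal
(FL) cassette, two autosomal EGI loci (a refactored *pyramus* promoter that the
programmable transcriptional activator cannot bind, and the PTA itself), and an
optional autosomal dominant-lethal (RIDL) locus. All four loci sit on distinct
chromosomes, so gametes form by independent assortment and crosses are exact
Punnett enumerations — no stochastic approximation is needed at this level.

Viability rules encoded here:

* EGI: one PTA copy is lethal (haplosufficient) unless the genome is
  homozygous for the promoter-resistance allele (haploinsufficient rescue);
  hybrids carrying PTA plus a wild-type promoter copy are inviable.
* FL: females carrying the FL cassette die unless tetracycline represses the
  circuit; the quantitative dose-response lives in :mod:`ssims.tet_dosimetry`.
* RIDL: dominant lethality in both sexes, repressed by dietary tetracycline.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterator

__all__ = [
    "X_ALLELES",
    "PYR_ALLELES",
    "PTA_ALLELES",
    "RIDL_ALLELES",
    "RIDL_TET_THRESHOLD",
    "Gamete",
    "Genotype",
    "enumerate_gametes",
    "fertilize",
    "egi_viable",
    "ridl_viable",
    "sex_of",
    "classify",
    "cross_distribution",
    "wt_female",
    "wt_male",
    "ssims_female",
    "ssims_male",
    "egi_female",
    "egi_male",
    "fl_female",
    "fl_male",
    "ridl_female",
    "ridl_male",
]

# Allowed allele symbols per locus. "+" is the unmodified allele everywhere.
X_ALLELES = frozenset({"FL", "+"})
PYR_ALLELES = frozenset({"res", "wt"})
PTA_ALLELES = frozenset({"PTA", "+"})
RIDL_ALLELES = frozenset({"RIDL", "+"})

#: Food-tetracycline concentration (μg/ml) at and above which the RIDL
#: lethal effector is repressed. Mirrors the hard floor of the FL
#: dose-response (`TetParams.e_floor` default).
RIDL_TET_THRESHOLD = 2.0


class InvalidGenotypeError(ValueError):
    """Raised for malformed genotypes, gametes, or impossible crosses."""


def _check_allele(value: str, allowed: frozenset, locus: str) -> None:
    if value not in allowed:
        raise InvalidGenotypeError(
            f"allele {value!r} not allowed at locus {locus} (allowed: {sorted(allowed)})"
        )


def _pair(a: str, b: str, allowed: frozenset, locus: str) -> tuple[str, str]:
    _check_allele(a, allowed, locus)
    _check_allele(b, allowed, locus)
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True, slots=True)
class Gamete:
    """A haploid gamete: one sex chromosome plus one allele per autosomal locus.

    ``x`` is the allele carried on the X chromosome, or ``None`` for a
    Y-bearing sperm.
    """

    x: str | None
    pyr: str
    pta: str
    ridl: str

    def __post_init__(self) -> None:
        if self.x is not None:
            _check_allele(self.x, X_ALLELES, "x")
        _check_allele(self.pyr, PYR_ALLELES, "pyr")
        _check_allele(self.pta, PTA_ALLELES, "pta")
        _check_allele(self.ridl, RIDL_ALLELES, "ridl")

    @property
    def bears_y(self) -> bool:
        return self.x is None


@dataclass(frozen=True, slots=True)
class Genotype:
    """Diploid genotype over the four engineered loci.

    ``x`` holds one allele for XY males and an unordered pair for XX females;
    the autosomal loci always hold unordered pairs. Pairs are normalised to
    sorted order so that equal genotypes compare and hash equal.
    """

    x: tuple[str, ...]
    pyr: tuple[str, str]
    pta: tuple[str, str]
    ridl: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.x) not in (1, 2):
            raise InvalidGenotypeError(
                f"x must hold 1 (XY) or 2 (XX) alleles, got {len(self.x)}"
            )
        for a in self.x:
            _check_allele(a, X_ALLELES, "x")
        object.__setattr__(self, "x", tuple(sorted(self.x)))
        object.__setattr__(self, "pyr", _pair(*self.pyr, PYR_ALLELES, "pyr"))
        object.__setattr__(self, "pta", _pair(*self.pta, PTA_ALLELES, "pta"))
        object.__setattr__(self, "ridl", _pair(*self.ridl, RIDL_ALLELES, "ridl"))

    # -- convenience predicates -------------------------------------------

    @property
    def karyotype(self) -> str:
        return "XX" if len(self.x) == 2 else "XY"

    @property
    def is_female(self) -> bool:
        return len(self.x) == 2

    @property
    def has_fl(self) -> bool:
        """At least one FL cassette on an X (dominant in females)."""
        return "FL" in self.x

    @property
    def has_pta(self) -> bool:
        return "PTA" in self.pta

    @property
    def has_ridl(self) -> bool:
        return "RIDL" in self.ridl

    @property
    def is_engineered(self) -> bool:
        """True if any engineered allele is present at any locus."""
        return (
            self.has_fl
            or self.has_pta
            or self.has_ridl
            or "res" in self.pyr
        )

    # -- string codec -------------------------------------------------------

    def to_string(self) -> str:
        """Compact round-trippable code, e.g. ``"XFL/Y;res,res;PTA,PTA;+,+"``."""
        if self.is_female:
            sex = f"X{self.x[0]}/X{self.x[1]}"
        else:
            sex = f"X{self.x[0]}/Y"
        return ";".join(
            [sex, ",".join(self.pyr), ",".join(self.pta), ",".join(self.ridl)]
        )

    @classmethod
    def from_string(cls, code: str) -> "Genotype":
        parts = code.strip().split(";")
        if len(parts) != 4:
            raise InvalidGenotypeError(f"genotype code needs 4 ';'-fields: {code!r}")
        sex, pyr_s, pta_s, ridl_s = parts
        chroms = sex.split("/")
        if len(chroms) != 2:
            raise InvalidGenotypeError(f"bad sex-chromosome field: {sex!r}")
        x_alleles: list[str] = []
        for c in chroms:
            if c == "Y":
                continue
            if not c.startswith("X"):
                raise InvalidGenotypeError(f"bad sex chromosome {c!r} in {code!r}")
            x_alleles.append(c[1:])
        if len(x_alleles) == 0:
            raise InvalidGenotypeError(f"no X chromosome in {code!r}")

        def split_pair(s: str, locus: str) -> tuple[str, str]:
            items = s.split(",")
            if len(items) != 2:
                raise InvalidGenotypeError(f"locus {locus} needs 2 alleles: {s!r}")
            return items[0], items[1]

        return cls(
            x=tuple(x_alleles),
            pyr=split_pair(pyr_s, "pyr"),
            pta=split_pair(pta_s, "pta"),
            ridl=split_pair(ridl_s, "ridl"),
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.to_string()


# ---------------------------------------------------------------------------
# Strain templates
# ---------------------------------------------------------------------------

def wt_female() -> Genotype:
    return Genotype(("+", "+"), ("wt", "wt"), ("+", "+"), ("+", "+"))


def wt_male() -> Genotype:
    return Genotype(("+",), ("wt", "wt"), ("+", "+"), ("+", "+"))


def ssims_female() -> Genotype:
    return Genotype(("FL", "FL"), ("res", "res"), ("PTA", "PTA"), ("+", "+"))


def ssims_male() -> Genotype:
    return Genotype(("FL",), ("res", "res"), ("PTA", "PTA"), ("+", "+"))


def egi_female() -> Genotype:
    return Genotype(("+", "+"), ("res", "res"), ("PTA", "PTA"), ("+", "+"))


def egi_male() -> Genotype:
    return Genotype(("+",), ("res", "res"), ("PTA", "PTA"), ("+", "+"))


def fl_female() -> Genotype:
    return Genotype(("FL", "FL"), ("wt", "wt"), ("+", "+"), ("+", "+"))


def fl_male() -> Genotype:
    return Genotype(("FL",), ("wt", "wt"), ("+", "+"), ("+", "+"))


def ridl_female() -> Genotype:
    return Genotype(("+", "+"), ("wt", "wt"), ("+", "+"), ("RIDL", "RIDL"))


def ridl_male() -> Genotype:
    return Genotype(("+",), ("wt", "wt"), ("+", "+"), ("RIDL", "RIDL"))


# ---------------------------------------------------------------------------
# Mendelian machinery
# ---------------------------------------------------------------------------

def enumerate_gametes(parent: Genotype) -> dict[Gamete, float]:
    """Exact gamete distribution under independent assortment.

    XX parents emit only X-bearing gametes; XY parents emit X- and Y-bearing
    gametes at probability 1/2 each. Probabilities sum to 1 and identical
    gametes are merged.
    """
    if not isinstance(parent, Genotype):
        raise InvalidGenotypeError(f"expected Genotype, got {type(parent).__name__}")
    if parent.is_female:
        sex_opts: list[str | None] = list(parent.x)
    else:
        sex_opts = [parent.x[0], None]  # None encodes the Y
    out: dict[Gamete, float] = {}
    n = len(sex_opts) * 2 * 2 * 2
    for sx, py, pt, rd in product(sex_opts, parent.pyr, parent.pta, parent.ridl):
        g = Gamete(x=sx, pyr=py, pta=pt, ridl=rd)
        out[g] = out.get(g, 0.0) + 1.0 / n
    return out


def fertilize(egg: Gamete, sperm: Gamete) -> Genotype:
    """Form a zygote; karyotype is XX iff the sperm carries an X."""
    if egg.bears_y:
        raise InvalidGenotypeError("egg cannot carry a Y chromosome")
    if sperm.bears_y:
        x: tuple[str, ...] = (egg.x,)  # type: ignore[assignment]
    else:
        x = (egg.x, sperm.x)  # type: ignore[arg-type]
    return Genotype(
        x=x,
        pyr=(egg.pyr, sperm.pyr),
        pta=(egg.pta, sperm.pta),
        ridl=(egg.ridl, sperm.ridl),
    )


def egi_viable(g: Genotype) -> bool:
    """EGI viability: inviable iff a PTA copy coexists with a wt pyr promoter.

    One PTA copy suffices for lethality; rescue requires homozygosity for the
    resistant promoter.
    """
    return not (g.has_pta and "wt" in g.pyr)


def ridl_viable(g: Genotype, food_tet: float) -> bool:
    """RIDL viability: a single lethal allele kills unless food Tet represses it."""
    if food_tet < 0:
        raise InvalidGenotypeError(f"negative tetracycline concentration: {food_tet}")
    return not (g.has_ridl and food_tet < RIDL_TET_THRESHOLD)


def sex_of(g: Genotype) -> str:
    """'female' for XX, 'male' for XY."""
    return "female" if g.is_female else "male"


def classify(g: Genotype) -> str:
    """Map a genotype to a strain label.

    WT: no engineered alleles. SSIMS: FL on every X plus homozygous EGI.
    EGI: homozygous EGI without FL. FL: FL-bearing without the PTA.
    RIDL: any RIDL allele. Everything else (hybrids, partial combinations)
    is OTHER.
    """
    if not g.is_engineered:
        return "WT"
    fl_on_every_x = all(a == "FL" for a in g.x)
    egi_homo = g.pyr == ("res", "res") and g.pta == ("PTA", "PTA")
    if g.has_ridl:
        return "RIDL"
    if fl_on_every_x and g.has_fl and egi_homo:
        return "SSIMS"
    if egi_homo and not g.has_fl:
        return "EGI"
    if g.has_fl and not g.has_pta:
        return "FL"
    return "OTHER"


def cross_distribution(
    mother: Genotype, father: Genotype
) -> list[tuple[Genotype, float, bool]]:
    """Exhaustive offspring distribution of a mother × father cross.

    Returns ``(genotype, probability, egi_viable)`` triples; probabilities sum
    to 1 over the zygote distribution (EGI-inviable zygotes are included with
    their flag set False — downstream layers decide when the death occurs).
    """
    if not mother.is_female:
        raise InvalidGenotypeError("mother must be XX")
    if father.is_female:
        raise InvalidGenotypeError("father must be XY")
    acc: dict[Genotype, float] = {}
    for egg, pe in enumerate_gametes(mother).items():
        for sperm, ps in enumerate_gametes(father).items():
            z = fertilize(egg, sperm)
            acc[z] = acc.get(z, 0.0) + pe * ps
    return [(g, p, egi_viable(g)) for g, p in sorted(acc.items(), key=lambda t: t[0].to_string())]


def all_genotypes() -> Iterator[Genotype]:
    """Every constructible genotype (135 total); used by exhaustive tests."""
    pairs = lambda alleles: [  # noqa: E731 - tiny local helper
        (a, b) for a, b in product(sorted(alleles), repeat=2) if a <= b
    ]
    x_opts = [(a,) for a in sorted(X_ALLELES)] + pairs(X_ALLELES)
    for x, py, pt, rd in product(
        x_opts, pairs(PYR_ALLELES), pairs(PTA_ALLELES), pairs(RIDL_ALLELES)
    ):
        yield Genotype(x=x, pyr=py, pta=pt, ridl=rd)
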