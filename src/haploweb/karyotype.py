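"""Robertsonian-fusion karyotype arithmetic.

A karyotype is modelled as an ancestral all-acrocentric complement
(``base_2n``, default 54) minus one chromosome per Robertsonian (Rb)
fusion copy carried.  Fusions change the diploid number but not the
fundamental number (arm count), so ``NF`` is stored, never derived.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Sequence

__all__ = [
    "RbTranslocation",
    "Karyotype",
    "KaryotypeError",
    "diploid_number",
    "parse_karyotype",
    "format_karyotype",
    "predict_f1",
    "diploid_number_range",
    "karyotype_consistency",
]

DEFAULT_BASE_2N = 54
DEFAULT_NF = 56


class KaryotypeError(ValueError):
    """Malformed karyotype formula or violated arm-usage constraint."""


@dataclass(frozen=True)
class RbTranslocation:
    """One Robertsonian fusion between two acrocentric autosome arms.

    ``arms`` is an unordered pair of arm identifiers; ``zygosity`` is the
    number of fused copies carried (1 = heterozygous, 2 = homozygous).
    Arm ids are strings so that non-homologous fusions from different
    lineages can be namespaced (e.g. ``t2`` vs ``2``).
    """

    arms: tuple[str, str]
    zygosity: int = 2

    def __post_init__(self) -> None:
        a, b = self.arms
        if a == b:
            raise KaryotypeError(f"Rb arms must be distinct, got ({a}.{b})")
        if self.zygosity not in (1, 2):
            raise KaryotypeError(f"zygosity must be 1 or 2, got {self.zygosity}")
        # canonical arm order: numeric if possible, else lexicographic
        object.__setattr__(self, "arms", tuple(sorted(self.arms, key=_arm_key)))

    def __str__(self) -> str:
        return f"{self.zygosity}Rb({self.arms[0]}.{self.arms[1]})"


def _arm_key(arm: str):
    return (0, int(arm)) if arm.isdigit() else (1, arm)


@dataclass(frozen=True)
class Karyotype:
    """A cytotype: base complement plus a set of Rb fusions with zygosity."""

    rbs: tuple[RbTranslocation, ...] = ()
    base_2n: int = DEFAULT_BASE_2N
    nf: int = DEFAULT_NF
    sex_system: str = "XX"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rb in self.rbs:
            for arm in rb.arms:
                if arm in seen:
                    raise KaryotypeError(f"arm {arm} used by more than one Rb")
                seen.add(arm)
        object.__setattr__(
            self, "rbs", tuple(sorted(self.rbs, key=lambda r: tuple(map(_arm_key, r.arms))))
        )

    @property
    def two_n(self) -> int:
        return diploid_number(self)

    def __str__(self) -> str:
        return format_karyotype(self)


def diploid_number(k: Karyotype) -> int:
    """2n = base complement minus one chromosome per fused copy."""
    return k.base_2n - sum(rb.zygosity for rb in k.rbs)


_RB_TOKEN = re.compile(r"^(\d)Rb\((\w+)\.(\w+)\)$")
_RB_RANGE_TOKEN = re.compile(r"^(\d)(?:[-–](\d))?Rb\((\w+)\.(\w+)\)$")


def parse_karyotype(formula: str, *, base_2n: int = DEFAULT_BASE_2N,
                    nf: int = DEFAULT_NF) -> Karyotype:
    """Parse a canonical formula like ``"2Rb(2.11),1Rb(3.10)"``.

    The empty string denotes the unfused base complement.  Round-trips
    through :func:`format_karyotype`.
    """
    formula = formula.strip()
    if not formula:
        return Karyotype(base_2n=base_2n, nf=nf)
    rbs = []
    for token in formula.split(","):
        m = _RB_TOKEN.match(token.strip())
        if not m:
            raise KaryotypeError(f"malformed Rb token: {token!r}")
        z, a, b = m.groups()
        rbs.append(RbTranslocation(arms=(a, b), zygosity=int(z)))
    return Karyotype(rbs=tuple(rbs), base_2n=base_2n, nf=nf)


def format_karyotype(k: Karyotype) -> str:
    return ",".join(str(rb) for rb in k.rbs)


def predict_f1(p1: Karyotype, p2: Karyotype) -> Karyotype:
    """Karyotype of the F1 of two Rb-homozygous parents.

    Each parent contributes one copy of every fusion it is homozygous
    for, so fusions shared by both parents come out homozygous and
    private ones heterozygous.  Heterozygous parents produce more than
    one gamete class and are rejected.
    """
    for p in (p1, p2):
        for rb in p.rbs:
            if rb.zygosity != 2:
                raise KaryotypeError(
                    f"parent carries heterozygous {rb}; F1 prediction requires "
                    "Rb-homozygous parents"
                )
    if p1.base_2n != p2.base_2n:
        raise KaryotypeError("parents must share the same base complement")
    arms1 = {rb.arms for rb in p1.rbs}
    arms2 = {rb.arms for rb in p2.rbs}
    rbs = [
        RbTranslocation(arms=arms, zygosity=2 if arms in arms1 and arms in arms2 else 1)
        for arms in sorted(arms1 | arms2, key=lambda p: tuple(map(_arm_key, p)))
    ]
    return Karyotype(rbs=tuple(rbs), base_2n=p1.base_2n, nf=p1.nf)


def diploid_number_range(formula: str, *, base_2n: int = DEFAULT_BASE_2N) -> tuple[int, int]:
    """(min, max) 2n for a formula that may carry ranged zygosity.

    Ranged tokens like ``"1-2Rb(3.10)"`` describe somatic mosaics; plain
    formulas collapse to a single-point range.
    """
    formula = formula.strip()
    if not formula:
        return (base_2n, base_2n)
    lo_total = hi_total = 0
    seen: set[str] = set()
    for token in formula.split(","):
        m = _RB_RANGE_TOKEN.match(token.strip())
        if not m:
            raise KaryotypeError(f"malformed Rb token: {token!r}")
        z1, z2, a, b = m.groups()
        zlo, zhi = int(z1), int(z2) if z2 else int(z1)
        if not (1 <= zlo <= zhi <= 2):
            raise KaryotypeError(f"zygosity range out of bounds in {token!r}")
        for arm in (a, b):
            if arm in seen:
                raise KaryotypeError(f"arm {arm} used by more than one Rb")
            seen.add(arm)
        lo_total += zhi
        hi_total += zlo
    return (base_2n - lo_total, base_2n - hi_total)


@dataclass
class ConsistencyRow:
    specimen_id: str
    stated_2n: tuple[int, int] | None
    computed_2n: tuple[int, int] | None
    consistent: bool | None
    note: str = ""


def karyotype_consistency(records: Sequence) -> list[ConsistencyRow]:
    """Check stated diploid numbers against Rb-derived ones.

    ``records`` are specimen metadata rows with ``specimen_id``,
    ``karyotype_formula`` (possibly ranged) and ``stated_2n`` (an int or
    (min, max) pair for mosaics); rows missing either field are reported
    as unscored.  A record is consistent when its stated range equals
    the computed one or lies inside it.
    """
    out: list[ConsistencyRow] = []
    for rec in records:
        formula = getattr(rec, "karyotype_formula", None)
        stated = getattr(rec, "stated_2n", None)
        sid = rec.specimen_id
        if formula is None or stated is None:
            out.append(ConsistencyRow(sid, _as_range(stated), None, None, "unscored"))
            continue
        computed = diploid_number_range(formula)
        srange = _as_range(stated)
        ok = computed[0] <= srange[0] and srange[1] <= computed[1]
        note = "" if ok else f"stated {srange} vs computed {computed}"
        out.append(ConsistencyRow(sid, srange, computed, ok, note))
    return out


def _as_range(stated) -> tuple[int, int] | None:
    if stated is None:
        return None
    if isinstance(stated, int):
        return (stated, stated)
    lo, hi = stated
    return (int(lo), int(hi))
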