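"""Proximate composition of a diet on a dry-matter basis.

Feed is characterised by the classic proximate fractions (ash, crude
protein, crude fat, crude fiber, all % of DM); the carbohydrate remainder
is the nitrogen-free extract (NFE), obtained by difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ProximateComposition:
    """One diet's proximate fractions.

    Parameters
    ----------
    dm : float
        Dry matter, % as-fed.
    ash, cp, ee, cf : float
        Ash, crude protein, crude fat (ether extract) and crude fiber,
        each as % of DM.

    The nitrogen-free extract ``nfe`` (% of DM) is derived on
    construction and never supplied.
    """

    dm: float
    ash: float
    cp: float
    ee: float
    cf: float
    nfe: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("dm", "ash", "cp", "ee", "cf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v!r} outside [0, 100]")
        object.__setattr__(self, "nfe", compute_nfe(self))


def compute_nfe(comp: "ProximateComposition | None" = None, *,
                ash: float | None = None, cp: float | None = None,
                ee: float | None = None, cf: float | None = None) -> float:
    """Nitrogen-free extract, % of DM, by difference.

    NFE = 100 - (ash + cp + ee + cf), all on a dry-matter basis: the
    non-fiber carbohydrate fraction left once the assayed fractions are
    subtracted from the whole of the dry matter.

    Accepts either a :class:`ProximateComposition` or the four fractions
    as keywords. Raises ``ValueError`` when the assayed fractions sum to
    more than 100 % of DM.
    """
    if comp is not None:
        ash, cp, ee, cf = comp.ash, comp.cp, comp.ee, comp.cf
    if None in (ash, cp, ee, cf):
        raise TypeError("supply a ProximateComposition or all of ash/cp/ee/cf")
    total = ash + cp + ee + cf  # type: ignore[operator]
    if total > 100.0 + 1e-9:
        raise ValueError(f"proximate fractions sum to {total:.4f} > 100 % DM")
    return 100.0 - total
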