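"""Collapsed substitution-type scheme shared by the error model and MRD test.

Single-nucleotide substitutions are collapsed into six strand-symmetric
classes keyed by a C or A reference: ``C-T, C-G, C-A, A-T, A-G, A-C``.
Substitutions whose reference base is a G or T are mapped to the reverse
complement class (``G>A`` is ``C-T``, ``T>C`` is ``A-G`` and so on), so the
class of a variant does not depend on which strand it was reported on.

C>T transitions at CpG dinucleotides (and their reverse complement, G>A with
a 5' C) are flagged separately: deamination of methylated cytosine makes them
both a dominant error mode and a common germline polymorphism, and the rest
of the pipeline excludes them from error-rate estimation and marker sets.
"""

from __future__ import annotations

from dataclasses import dataclass

VARIANT_TYPES: tuple[str, ...] = ("C-T", "C-G", "C-A", "A-T", "A-G", "A-C")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class VariantType:
    """One of the six collapsed substitution classes.

    Attributes
    ----------
    cls : str
        Collapsed class label, one of :data:`VARIANT_TYPES`.
    cpg_ct : bool
        True when the substitution is a C>T at a CpG site on either strand.
    """

    cls: str
    cpg_ct: bool = False

    def __post_init__(self) -> None:
        if self.cls not in VARIANT_TYPES:
            raise ValueError(f"unknown variant class {self.cls!r}")
        if self.cpg_ct and self.cls != "C-T":
            raise ValueError("cpg_ct only applies to the C-T class")


def classify_substitution(
    ref_base: str, alt_base: str, trinucleotide_context: str | None = None
) -> VariantType:
    """Collapse a substitution into the six-class scheme.

    Parameters
    ----------
    ref_base, alt_base : str
        Single upper-case bases; must differ and be unambiguous (no N).
    trinucleotide_context : str, optional
        5'->3' trinucleotide centered on the reference base, used only to
        decide the CpG C>T flag. When omitted the flag is False.

    Returns
    -------
    VariantType
    """
    ref = ref_base.upper()
    alt = alt_base.upper()
    if ref not in _VALID or alt not in _VALID:
        raise ValueError(f"ambiguous or invalid base in substitution {ref_base}>{alt_base}")
    if ref == alt:
        raise ValueError(f"not a substitution: {ref}>{alt}")

    if ref in "GT":
        cls = f"{_COMPLEMENT[ref]}-{_COMPLEMENT[alt]}"
    else:
        cls = f"{ref}-{alt}"

    cpg = False
    if trinucleotide_context is not None:
        ctx = trinucleotide_context.upper()
        if len(ctx) != 3:
            raise ValueError("trinucleotide context must have length 3")
        if ctx[1] != ref:
            raise ValueError(
                f"context {ctx!r} center does not match reference base {ref!r}"
            )
        # CpG C>T: plus-strand C with 3' G, or its reverse complement G>A with 5' C.
        if ref == "C" and alt == "T" and ctx[2] == "G":
            cpg = True
        elif ref == "G" and alt == "A" and ctx[0] == "C":
            cpg = True

    return VariantType(cls=cls, cpg_ct=cpg)


def collapsed_reference(ref_base: str) -> str:
    """Collapse a reference base to the C/A convention ('C' for C/G, 'A' for A/T)."""
    ref = ref_base.upper()
    if ref not in _VALID:
        raise ValueError(f"invalid reference base {ref_base!r}")
    return "C" if ref in "CG" else "A"


def types_for_reference(ref_base: str) -> tuple[str, str, str]:
    """The three substitution classes a reference base can mutate into."""
    c = collapsed_reference(ref_base)
    return tuple(t for t in VARIANT_TYPES if t.startswith(c))  # type: ignore[return-value]
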