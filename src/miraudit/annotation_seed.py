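"""miRNA annotation semantics: seeds, seed families, family-summed expression.

A mature miRNA recognises targets primarily through its seed, the nucleotides
at its 5' end. Two seed definitions are carried side by side:

* ``seed6`` — nucleotides 2–7 (1-based, inclusive), the 6-mer that defines
  co-targeting families: every mature sharing this 6-mer is expected to
  repress a reporter carrying a complementary site.
* ``seed8`` — nucleotides 2–9, the 8-nt site used when describing seed-only
  reporter constructs.

The family key is always the 6-mer; the 8-nt seed is descriptive bookkeeping
only. Family-summed expression ("Seed" alongside "Exact") quantifies the
total dose of a reporter's seed family in a given expression profile.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

from .errors import ValidationError

ARMS = ("5p", "3p", "unknown")
DROSHA_CLASSES = ("good", "poor", "unknown")

_RNA_COMPLETE = set("ACGU")


def extract_seed(sequence: str, start_pos: int, end_pos: int) -> str:
    """Return the subsequence at 1-based inclusive positions, as RNA.

    The sequence is uppercased and DNA ``T`` is mapped to ``U`` before
    slicing, so annotation tables exported as DNA are handled transparently.

    Raises
    ------
    ValidationError
        If the positions are out of order, non-positive, or run past the end
        of the sequence.
    """
    if start_pos < 1 or end_pos < start_pos:
        raise ValidationError(
            f"invalid seed positions {start_pos}..{end_pos}: need 1 <= start <= end"
        )
    seq = normalize_rna(sequence)
    if end_pos > len(seq):
        raise ValidationError(
            f"sequence of length {len(seq)} too short for seed positions "
            f"{start_pos}..{end_pos}"
        )
    return seq[start_pos - 1 : end_pos]


def normalize_rna(sequence: str) -> str:
    """Uppercase and convert T to U."""
    return sequence.strip().upper().replace("T", "U")


@dataclass(frozen=True)
class MirnaAnnotation:
    """One mature miRNA: identity, locus, sequence and curation metadata.

    ``mirgenedb_member`` is True/False when the curation status is known and
    ``None`` when it is not. ``taxon_node`` names the oldest lineage in which
    the locus is annotated ("unknown" if unannotated); ``taxon_age_mya`` is
    the corresponding divergence age in million years. ``drosha_class`` is a
    pass-through good/poor processing label taken from published data, never
    recomputed here.
    """

    mature_id: str
    locus_id: str
    arm: str
    sequence: str
    mirgenedb_member: bool | None = None
    taxon_node: str = "unknown"
    taxon_age_mya: float | None = None
    drosha_class: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if self.arm not in ARMS:
            raise ValidationError(
                f"{self.mature_id}: arm must be one of {ARMS}, got {self.arm!r}"
            )
        if len(self.sequence) < 16:
            raise ValidationError(
                f"{self.mature_id}: mature sequence must be >= 16 nt, "
                f"got {len(self.sequence)}"
            )
        bad = set(self.sequence) - _RNA_COMPLETE
        if bad:
            raise ValidationError(
                f"{self.mature_id}: sequence contains non-ACGU characters {sorted(bad)}"
            )
        if self.drosha_class not in DROSHA_CLASSES:
            raise ValidationError(
                f"{self.mature_id}: drosha_class must be one of {DROSHA_CLASSES}, "
                f"got {self.drosha_class!r}"
            )
        if self.taxon_age_mya is not None and self.taxon_age_mya < 0:
            raise ValidationError(f"{self.mature_id}: taxon_age_mya must be >= 0")

    @property
    def seed6(self) -> str:
        """Nucleotides 2–7, the family-defining 6-mer."""
        return extract_seed(self.sequence, 2, 7)

    @property
    def seed8(self) -> str:
        """Nucleotides 2–9, the 8-nt reporter seed site."""
        return extract_seed(self.sequence, 2, 9)


@dataclass(frozen=True)
class SeedFamily:
    """All mature miRNAs sharing one nt 2–7 seed."""

    seed6: str
    member_ids: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.member_ids)


def build_seed_families(annotations: Iterable[MirnaAnnotation]) -> list[SeedFamily]:
    """Partition mature miRNAs into families keyed by the nt 2–7 seed.

    A mature annotated at several loci (identical sequence, paralogous
    hairpins) counts once. Families are returned sorted by seed for
    determinism; singleton families are legitimate.
    """
    members: dict[str, set[str]] = {}
    for ann in annotations:
        members.setdefault(ann.seed6, set()).add(ann.mature_id)
    return [
        SeedFamily(seed6=k, member_ids=frozenset(v))
        for k, v in sorted(members.items())
    ]


def seed_family_expression(
    target_mature_id: str,
    annotations: Iterable[MirnaAnnotation],
    expression: Mapping[str, float],
    include_target: bool = True,
) -> tuple[float, float]:
    """Exact and seed-family-summed expression for one reporter target.

    Parameters
    ----------
    target_mature_id
        The mature miRNA the reporter was designed against.
    annotations
        Annotation records defining seed families.
    expression
        Per-mature cpm for one sample (or a per-mature maximum vector);
        any mapping, e.g. a ``pandas.Series`` indexed by mature id.
    include_target
        If True (default) the family sum includes the target itself, i.e.
        the total expression of everything expected to repress the reporter.
        If False, only the increment from other family members is returned.

    Returns
    -------
    (exact_cpm, seed_cpm)
        ``exact_cpm`` is the target's own cpm (0 with a warning when the
        target is absent from the expression vector); ``seed_cpm`` sums over
        the target's whole seed6 family. With ``include_target`` the sum is
        always >= ``exact_cpm``.
    """
    anns = list(annotations)
    target = next((a for a in anns if a.mature_id == target_mature_id), None)
    if target is None:
        raise ValidationError(f"target {target_mature_id!r} not in annotations")

    if target_mature_id in expression:
        exact = float(expression[target_mature_id])
    else:
        warnings.warn(
            f"target {target_mature_id!r} absent from expression vector; "
            "exact_cpm set to 0",
            stacklevel=2,
        )
        exact = 0.0

    family_ids = {a.mature_id for a in anns if a.seed6 == target.seed6}
    seed = float(
        sum(float(expression[m]) for m in family_ids if m in expression)
    )
    if not include_target:
        seed -= exact
    return exact, seed
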