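"""Cas enzyme registry and IUPAC PAM-motif algebra.

A Cas nuclease is characterized here by its PAM (protospacer adjacent motif),
written in the IUPAC degenerate nucleotide alphabet (e.g. ``NGG`` for SpCas9,
``NNGRRT`` for SaCas9), by which side of the protospacer the PAM sits on
(3' for Cas9-family enzymes, 5' for Cas12a/Cpf1-family), and by the
protospacer length the sgRNA spacer hybridizes to (20 nt by default).

The motif algebra in this module — IUPAC window matching, motif reverse
complement and PAM "size" (number of constrained, i.e. non-N, positions) —
underpins every downstream scanning and design step.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "IUPAC",
    "CasEnzyme",
    "CasRegistry",
    "pam_size",
    "motif_matches",
    "reverse_complement_motif",
    "reverse_complement",
    "load_registry",
    "load_default_registry",
]

#: IUPAC degenerate nucleotide codes mapped to the set of bases they allow.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Complement of each IUPAC code (A<->T, C<->G, R<->Y, K<->M, B<->V, D<->H;
#: S, W and N are self-complementary).
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "S": "S", "W": "W", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

PAM_SIDES = ("three_prime", "five_prime")


class RegistryError(ValueError):
    """A Cas registry config entry failed validation."""


def _validate_motif(motif: str) -> str:
    motif = motif.upper()
    if not motif:
        raise RegistryError("PAM motif must be non-empty")
    bad = sorted(set(motif) - IUPAC.keys())
    if bad:
        raise RegistryError(f"invalid IUPAC character(s) {bad!r} in motif {motif!r}")
    return motif


@dataclass(frozen=True)
class CasEnzyme:
    """A Cas nuclease: PAM motif, PAM orientation and protospacer length.

    ``pam_side`` is the position of the PAM relative to the protospacer on
    the protospacer's strand: ``three_prime`` (SpCas9-like) or ``five_prime``
    (Cas12a-like).
    """

    name: str
    pam_motif: str
    pam_side: str = "three_prime"
    protospacer_length: int = 20

    def __post_init__(self) -> None:
        if not self.name:
            raise RegistryError("Cas enzyme needs a non-empty name")
        object.__setattr__(self, "pam_motif", _validate_motif(self.pam_motif))
        if self.pam_side not in PAM_SIDES:
            raise RegistryError(
                f"{self.name}: pam_side must be one of {PAM_SIDES}, got {self.pam_side!r}"
            )
        if not isinstance(self.protospacer_length, int) or self.protospacer_length < 1:
            raise RegistryError(
                f"{self.name}: protospacer_length must be a positive integer"
            )

    @property
    def pam_length(self) -> int:
        return len(self.pam_motif)

    @property
    def size(self) -> int:
        """Number of constrained (non-N) PAM positions."""
        return pam_size(self.pam_motif)


def pam_size(motif: str) -> int:
    """Count of constrained PAM positions: every character that is not 'N'.

    Degenerate non-N codes (R, Y, ...) constrain the base and therefore
    count. ``NGG`` -> 2, ``NNGRRT`` -> 4.
    """
    motif = _validate_motif(motif)
    return sum(1 for c in motif if c != "N")


def motif_matches(motif: str, window: str) -> bool:
    """True iff every base of ``window`` is allowed by the aligned IUPAC code.

    The window must have the motif's length and is handled case-insensitively.
    A window character outside {A, C, G, T} (e.g. an assembly 'N') never
    matches, even against a motif 'N': an unknown base cannot be confirmed
    as part of a PAM.
    """
    motif = _validate_motif(motif)
    if len(window) != len(motif):
        raise ValueError(
            f"window length {len(window)} != motif length {len(motif)}"
        )
    window = window.upper()
    for code, base in zip(motif, window):
        if base not in IUPAC[code]:
            return False
    return True


def reverse_complement_motif(motif: str) -> str:
    """Reverse complement of an IUPAC motif (an involution)."""
    motif = _validate_motif(motif)
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(motif))


def reverse_complement(seq: str) -> str:
    """Reverse complement of a plain DNA sequence; non-ACGT bases become 'N'."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp.get(c, "N") for c in reversed(seq.upper()))


class CasRegistry(Mapping[str, CasEnzyme]):
    """An ordered, name-unique collection of :class:`CasEnzyme`."""

    def __init__(self, enzymes: Iterable[CasEnzyme]) -> None:
        self._enzymes: dict[str, CasEnzyme] = {}
        for enz in enzymes:
            if enz.name in self._enzymes:
                raise RegistryError(f"duplicate Cas enzyme name {enz.name!r}")
            self._enzymes[enz.name] = enz

    def __getitem__(self, name: str) -> CasEnzyme:
        return self._enzymes[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._enzymes)

    def __len__(self) -> int:
        return len(self._enzymes)

    @property
    def enzymes(self) -> list[CasEnzyme]:
        return list(self._enzymes.values())


def _registry_from_records(records: Iterable[dict]) -> CasRegistry:
    enzymes = []
    for rec in records:
        try:
            enzymes.append(
                CasEnzyme(
                    name=str(rec["name"]),
                    pam_motif=str(rec["pam_motif"]),
                    pam_side=str(rec.get("pam_side", "three_prime")),
                    protospacer_length=int(rec.get("protospacer_length", 20)),
                )
            )
        except RegistryError:
            raise
        except (KeyError, TypeError, ValueError) as exc:
            raise RegistryError(f"malformed Cas config entry {rec!r}: {exc}") from exc
    return CasRegistry(enzymes)


def load_registry(path: str | Path) -> CasRegistry:
    """Load a Cas registry from a YAML file (list of enzyme mappings)."""
    with open(path) as fh:
        records = yaml.safe_load(fh)
    if not isinstance(records, list):
        raise RegistryError(f"{path}: expected a YAML list of enzyme entries")
    return _registry_from_records(records)


def load_default_registry() -> CasRegistry:
    """The shipped default registry of 11 commonly used Cas enzymes.

    Includes SpCas9 (NGG), SaCas9 (NNGRRT) and two 5'-PAM Cas12a enzymes;
    see data/cas_enzymes.yaml. Users extend or replace it via
    :func:`load_registry`.
    """
    ref = resources.files("allelescan.data").joinpath("cas_enzymes.yaml")
    records = yaml.safe_load(ref.read_text())
    return _registry_from_records(records)
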