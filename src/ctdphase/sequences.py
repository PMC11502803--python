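"""CTD construct building.

The human RNA polymerase II CTD is a tandem array of the consensus heptad
Y1-S2-P3-T4-S5-P6-S7 (52 repeats in the full-length domain), preceded here,
as in the recombinant constructs, by a short Pro-Ser prefix.  This module
builds the consensus and the variant set studied experimentally, applies
phospho-marks to serines at heptad positions 5 or 7, assigns cis/trans
isomer states to the position-3/6 (hydroxy)prolines, and locates SPXX
motifs, the four-residue segments whose compact state corresponds to a
beta-turn.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

CONSENSUS = ("Y", "S", "P", "T", "S", "P", "S")
PREFIX = ("P", "S")

#: variants that could not be expressed solubly; constructible, but flagged.
INSOLUBLE_VARIANTS = {"P6G", "P3,6G"}

_SUPPORTED = [
    "cons", "Y1F", "Y1A", "P3G", "T4G", "S2A", "S5A", "S7A",
    "S2,5A", "S2,7A", "S5,7A", "S2,5,7A", "Hyp", "pS5", "pS7",
    "P6G", "P3,6G",
]

_LABEL_RE = re.compile(r"^([YSPT])(\d(?:,\d)*)([A-Z])$")


@dataclass(frozen=True)
class ResidueSpec:
    """One bead-resolution residue.

    code : one-letter code; 'O' denotes trans-4-hydroxyproline.
    heptad_position : 1-7 within the repeat, 0 for the Pro-Ser prefix.
    is_phospho : phosphoserine flag (serine only).
    phospho_charge : -1 or -1.5 elementary charges when phosphorylated.
    isomer : 'cis' or 'trans' for P/O residues, None otherwise.
    """

    code: str
    heptad_position: int
    is_phospho: bool = False
    phospho_charge: float | None = None
    isomer: str | None = None

    def __post_init__(self):
        if self.is_phospho and self.code != "S":
            raise ValueError("phosphorylation is only defined for serine")
        if self.is_phospho and self.phospho_charge not in (-1.0, -1.5):
            raise ValueError("phospho_charge must be -1 or -1.5")
        if (self.isomer is not None) != (self.code in ("P", "O")):
            raise ValueError("isomer state applies exactly to P/O residues")
        if self.isomer not in (None, "cis", "trans"):
            raise ValueError(f"unknown isomer state {self.isomer!r}")


def _make_residue(code: str, heptad_position: int) -> ResidueSpec:
    isomer = "trans" if code in ("P", "O") else None
    return ResidueSpec(code=code, heptad_position=heptad_position, isomer=isomer)


@dataclass(frozen=True)
class CTDSequence:
    """An annotated CTD construct: PS prefix followed by n_repeats heptads."""

    residues: tuple[ResidueSpec, ...]
    n_repeats: int
    variant_label: str

    def __post_init__(self):
        if len(self.residues) != 2 + 7 * self.n_repeats:
            raise ValueError("length must be 2 + 7 * n_repeats")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def codes(self) -> str:
        return "".join(r.code for r in self.residues)

    @property
    def net_charge(self) -> float:
        return sum(r.phospho_charge for r in self.residues if r.is_phospho)

    def count(self, code: str) -> int:
        return sum(1 for r in self.residues if r.code == code)

    def heptad(self, repeat: int) -> tuple[ResidueSpec, ...]:
        """Residues of one repeat (0-based repeat index)."""
        start = 2 + 7 * repeat
        return self.residues[start:start + 7]


def _parse_variant(label: str) -> dict[int, str]:
    """Map heptad position -> substituted code for a variant label."""
    if label in ("cons", "pS5", "pS7"):
        return {}
    if label == "Hyp":
        return {3: "O", 6: "O"}
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(
            f"unknown variant label {label!r}; supported: {', '.join(_SUPPORTED)}"
        )
    base, positions, new = m.group(1), m.group(2), m.group(3)
    subs = {}
    for p in positions.split(","):
        pos = int(p)
        if not 1 <= pos <= 7 or CONSENSUS[pos - 1] != base:
            raise ValueError(
                f"variant label {label!r} does not match the consensus heptad "
                f"{''.join(CONSENSUS)}"
            )
        subs[pos] = new
    return subs


def build_ctd(variant_label: str, n_repeats: int) -> CTDSequence:
    """Build a PS-prefixed CTD construct with a substitution in every repeat.

    Parameters
    ----------
    variant_label : one of cons, Y1F, Y1A, P3G, T4G, S2A, S5A, S7A, S2,5A,
        S2,7A, S5,7A, S2,5,7A, Hyp, pS5, pS7 (plus the experimentally
        insoluble P6G and P3,6G, built with a warning).
    n_repeats : number of heptad repeats (52 for the full-length domain).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if variant_label not in _SUPPORTED:
        # raise the informative error from the parser
        _parse_variant(variant_label)
    if variant_label in INSOLUBLE_VARIANTS:
        warnings.warn(
            f"variant {variant_label} yielded only insoluble material "
            "experimentally; it is built here for completeness",
            stacklevel=2,
        )
    subs = _parse_variant(variant_label)
    residues = [_make_residue(c, 0) for c in PREFIX]
    for _ in range(n_repeats):
        for pos in range(1, 8):
            code = subs.get(pos, CONSENSUS[pos - 1])
            residues.append(_make_residue(code, pos))
    seq = CTDSequence(tuple(residues), n_repeats, variant_label)
    if variant_label == "pS5":
        seq = apply_phosphorylation(seq, 5, -1.0)
    elif variant_label == "pS7":
        seq = apply_phosphorylation(seq, 7, -1.0)
    return seq


def apply_phosphorylation(seq: CTDSequence, target_position: int,
                          charge: float = -1.0) -> CTDSequence:
    """Phosphorylate the serine at a heptad position in every repeat.

    The phosphate is represented downstream as a charged side bead (-1e or
    -1.5e, mimicking singly/doubly deprotonated phosphoserine).
    """
    if target_position not in (5, 7):
        raise ValueError("phosphorylation target must be heptad position 5 or 7")
    if charge not in (-1.0, -1.5):
        raise ValueError("charge must be -1 or -1.5")
    new = []
    for r in seq.residues:
        if r.heptad_position == target_position:
            if r.code != "S":
                raise ValueError(
                    f"residue at heptad position {target_position} is "
                    f"{r.code}, not serine; cannot phosphorylate "
                    f"variant {seq.variant_label!r}"
                )
            r = replace(r, is_phospho=True, phospho_charge=float(charge))
        new.append(r)
    return CTDSequence(tuple(new), seq.n_repeats, seq.variant_label)


_PATTERNS = {"trans-trans": ("trans", "trans"), "cis-trans": ("cis", "trans"),
             "trans-cis": ("trans", "cis"), "cis-cis": ("cis", "cis")}


def assign_proline_isomers(seq: CTDSequence, pattern: str) -> CTDSequence:
    """Set the isomer state of position-3 and position-6 (hydroxy)prolines.

    ``pattern`` names the state of the position-3 then position-6 residue,
    e.g. 'cis-trans'.  Variants without a proline at a position (P3G) simply
    have nothing to flag there.  The prefix proline keeps its trans state.
    """
    if pattern not in _PATTERNS:
        raise ValueError(f"pattern must be one of {sorted(_PATTERNS)}")
    state3, state6 = _PATTERNS[pattern]
    new = []
    for r in seq.residues:
        if r.code in ("P", "O") and r.heptad_position == 3:
            r = replace(r, isomer=state3)
        elif r.code in ("P", "O") and r.heptad_position == 6:
            r = replace(r, isomer=state6)
        new.append(r)
    return CTDSequence(tuple(new), seq.n_repeats, seq.variant_label)


def find_spxx_motifs(seq: CTDSequence) -> list[int]:
    """0-based start indices of SPXX motifs.

    A motif starts at i when residue i is serine (phospho or not), residue
    i+1 is proline or hydroxyproline, and residues i+2, i+3 exist.  A
    consensus construct of n repeats carries 2n - 1 motifs (S2-P3-T4-S5 in
    every repeat plus the bridging S5-P6-S7-Y1 in all but the last).
    """
    codes = [r.code for r in seq.residues]
    n = len(codes)
    return [i for i in range(n - 3)
            if codes[i] == "S" and codes[i + 1] in ("P", "O")]


def to_fasta(seqs: CTDSequence | list[CTDSequence], fasta_path,
             annotations_path=None) -> None:
    """Write constructs as FASTA plus an optional annotation sidecar CSV.

    FASTA cannot carry phospho or isomer marks, so those go in the CSV
    (one row per residue).  Hydroxyproline is written as 'O' (a letter
    officially assigned to pyrrolysine, reused here as the spec'd code).
    """
    if isinstance(seqs, CTDSequence):
        seqs = [seqs]
    with open(fasta_path, "w") as fh:
        for s in seqs:
            fh.write(f">CTD_{s.variant_label}_x{s.n_repeats}\n")
            codes = s.codes()
            for i in range(0, len(codes), 60):
                fh.write(codes[i:i + 60] + "\n")
    if annotations_path is not None:
        rows = []
        for s in seqs:
            for i, r in enumerate(s.residues):
                rows.append({
                    "variant": s.variant_label, "index": i, "code": r.code,
                    "heptad_position": r.heptad_position,
                    "is_phospho": r.is_phospho,
                    "phospho_charge": r.phospho_charge,
                    "isomer": r.isomer if r.isomer is not None else "n/a",
                })
        pd.DataFrame(rows).to_csv(annotations_path, index=False)
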