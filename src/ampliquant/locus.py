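"""Target loci, classification reference windows and HDR donor templates.

A target locus is a 20-nt protospacer plus 3-nt PAM embedded (on either
strand) in a PCR amplicon.  S. pyogenes Cas9 cleaves bluntly 3 bp 5' of the
PAM, i.e. between protospacer offsets 16 and 17 — inter-base index 17 on the
protospacer strand.  Per-read classification is performed against a short
reference window centred on the target: the 23-nt protospacer+PAM plus
``flank`` nt of genomic context on each side (53 nt with the default
``flank=15``).

Coordinate conventions
----------------------
All coordinates are 0-based, half-open.  Cut sites are *inter-base* indices:
a cut at index ``c`` falls between bases ``c-1`` and ``c``.  Reference
windows are reported in protospacer-strand orientation; amplicon coordinates
are always plus-strand.  HDR template edits (insert, deletion) are declared
in amplicon plus-strand frame; :func:`insert_in_window_frame` maps the
diagnostic insert into the window frame for minus-strand loci.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq

# Cas9 blunt cut: 3 nt 5' of the PAM on the protospacer strand.
CUT_OFFSET_IN_PROTOSPACER = 17

IUPAC_LETTERS = set("ACGTRYSWKMBDHVN")


class AmbiguousTargetError(ValueError):
    """Protospacer+PAM absent, or present more than once, in the amplicon."""


class WindowOutOfBoundsError(ValueError):
    """Amplicon lacks the flanking context needed for the reference window."""


class TemplateInconsistentError(ValueError):
    """HDR template homology arm disagrees with the amplicon."""


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _clean(seq: str) -> str:
    seq = seq.strip().upper().replace("U", "T")
    bad = set(seq) - IUPAC_LETTERS
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class TargetLocus:
    """One Cas9 target site in its amplicon context.

    ``strand`` is the strand of the protospacer within the amplicon; the
    protospacer+PAM must occur exactly once on that strand.
    """

    name: str
    protospacer: str
    pam: str
    amplicon: str
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "protospacer", _clean(self.protospacer))
        object.__setattr__(self, "pam", _clean(self.pam))
        object.__setattr__(self, "amplicon", _clean(self.amplicon))
        if len(self.protospacer) != 20:
            raise ValueError(f"protospacer must be 20 nt, got {len(self.protospacer)}")
        if len(self.pam) != 3:
            raise ValueError(f"PAM must be 3 nt, got {len(self.pam)}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.pam[1:] != "GG":
            warnings.warn(
                f"{self.name}: PAM {self.pam} is not NGG; Cas9 cleavage is "
                "unlikely at non-canonical PAMs",
                stacklevel=2,
            )
        self._target_start()  # uniqueness check

    @property
    def target(self) -> str:
        """Protospacer+PAM (23 nt) in protospacer-strand orientation."""
        return self.protospacer + self.pam

    def strand_sequence(self) -> str:
        """The amplicon in protospacer-strand orientation."""
        return self.amplicon if self.strand == "+" else revcomp(self.amplicon)

    def _target_start(self) -> int:
        """Start of the 23-nt target within :meth:`strand_sequence`."""
        seq = self.strand_sequence()
        n = seq.count(self.target)
        if n == 0:
            raise AmbiguousTargetError(
                f"{self.name}: target {self.target} not found on strand "
                f"{self.strand} of the amplicon"
            )
        if n > 1:
            raise AmbiguousTargetError(
                f"{self.name}: target occurs {n} times in the amplicon"
            )
        return seq.index(self.target)


@dataclass(frozen=True)
class ReferenceWindow:
    """Target-centred reference for per-read classification.

    ``cut_index`` is the inter-base cut coordinate within ``sequence``;
    ``expected_insert`` is the HDR diagnostic key in window (protospacer
    strand) frame, empty when no HDR reporting is wanted.
    """

    sequence: str
    cut_index: int
    expected_insert: str = ""
    flank: int = 15

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _clean(self.sequence))
        if self.expected_insert:
            object.__setattr__(self, "expected_insert", _clean(self.expected_insert))
        if len(self.sequence) != 23 + 2 * self.flank:
            raise ValueError(
                f"window length {len(self.sequence)} != 23 + 2*{self.flank}"
            )
        if not 0 < self.cut_index < len(self.sequence):
            raise ValueError(f"cut_index {self.cut_index} outside window")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HdrTemplate:
    """A donor template: homology arms flanking an intended edit.

    ``insert``/``deletion_len`` describe the edit in amplicon plus-strand
    frame at the cut site (deletion removes bases immediately 3' of the cut).
    ``orientation`` '-' means ``sequence`` is the reverse complement of the
    plus-strand design, as with donor oligos synthesised complementary to
    the target strand.
    """

    sequence: str
    orientation: str = "+"
    left_arm: int = 0
    right_arm: int = 0
    insert: str = ""
    deletion_len: int = 0
    double_stranded: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _clean(self.sequence))
        if self.insert:
            object.__setattr__(self, "insert", _clean(self.insert))
        if self.orientation not in "+-":
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")
        if self.left_arm < 0 or self.right_arm < 0 or self.deletion_len < 0:
            raise ValueError("arm lengths and deletion_len must be >= 0")
        if not self.sequence:
            raise ValueError("template sequence is empty")

    def plus_strand_sequence(self) -> str:
        return self.sequence if self.orientation == "+" else revcomp(self.sequence)


@dataclass(frozen=True)
class TemplateReport:
    """Result of checking a donor template against its locus."""

    left_arm: int
    right_arm: int
    insert_len: int
    deletion_len: int
    edited_allele: str

    @property
    def edit_len(self) -> int:
        return self.insert_len + self.deletion_len


def locate_cut_site(locus: TargetLocus) -> int:
    """Blunt Cas9 cut site as an inter-base amplicon (plus-strand) index.

    The cut falls 3 nt 5' of the PAM, between protospacer offsets 16 and 17.
    For minus-strand loci the protospacer-strand coordinate is mapped back
    into plus-strand amplicon coordinates.
    """
    cut_on_strand = locus._target_start() + CUT_OFFSET_IN_PROTOSPACER
    if locus.strand == "+":
        return cut_on_strand
    return len(locus.amplicon) - cut_on_strand


def build_reference_window(
    locus: TargetLocus, flank: int = 15, expected_insert: str = ""
) -> ReferenceWindow:
    """Slice the classification window around the target.

    The window is ``flank + protospacer + PAM + flank`` in protospacer-strand
    orientation; ``expected_insert`` must already be in window frame (see
    :func:`insert_in_window_frame`).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    seq = locus.strand_sequence()
    start = locus._target_start()
    lo, hi = start - flank, start + 23 + flank
    if lo < 0 or hi > len(seq):
        raise WindowOutOfBoundsError(
            f"{locus.name}: amplicon provides only {start} nt upstream and "
            f"{len(seq) - start - 23} nt downstream of the target; "
            f"flank={flank} requested"
        )
    return ReferenceWindow(
        sequence=seq[lo:hi],
        cut_index=flank + CUT_OFFSET_IN_PROTOSPACER,
        expected_insert=expected_insert,
        flank=flank,
    )


def insert_in_window_frame(locus: TargetLocus, insert: str) -> str:
    """Map an amplicon plus-strand insert into window (protospacer) frame."""
    return insert if locus.strand == "+" else revcomp(insert)


def edited_allele(locus: TargetLocus, insert: str = "", deletion_len: int = 0) -> str:
    """Amplicon with the HDR edit applied at the cut site (plus-strand frame)."""
    return apply_edit(
        locus.amplicon, locate_cut_site(locus), _clean(insert) if insert else "", deletion_len
    )


def apply_edit(amplicon: str, cut: int, insert: str = "", deletion_len: int = 0) -> str:
    """Insert ``insert`` at inter-base index ``cut`` and delete ``deletion_len``
    bases immediately 3' of it."""
    if deletion_len < 0 or cut + deletion_len > len(amplicon):
        raise ValueError("deletion extends past the amplicon")
    return amplicon[:cut] + insert + amplicon[cut + deletion_len :]


def validate_hdr_template(template: HdrTemplate, locus: TargetLocus) -> TemplateReport:
    """Check a donor template against the amplicon and reconstruct the edit.

    The template (normalised to plus strand) must read
    ``left arm | insert | right arm`` where the arms match the amplicon
    exactly on either side of the cut (the right arm starts after the
    declared deletion).  Returns the verified geometry and the edited
    allele; raises :class:`TemplateInconsistentError` at the first arm base
    that disagrees with the amplicon.
    """
    seq = template.plus_strand_sequence()
    cut = locate_cut_site(locus)
    ins = template.insert
    expected_len = template.left_arm + len(ins) + template.right_arm
    if len(seq) != expected_len:
        raise TemplateInconsistentError(
            f"template length {len(seq)} != left_arm + insert + right_arm = {expected_len}"
        )
    if template.left_arm > cut:
        raise TemplateInconsistentError("left arm extends past the amplicon 5' end")
    right_start = cut + template.deletion_len
    if right_start + template.right_arm > len(locus.amplicon):
        raise TemplateInconsistentError("right arm extends past the amplicon 3' end")

    left_ref = locus.amplicon[cut - template.left_arm : cut]
    left_obs = seq[: template.left_arm]
    for i, (x, y) in enumerate(zip(left_obs, left_ref)):
        if x != y:
            raise TemplateInconsistentError(
                f"left arm mismatch at template position {i}: {x} vs amplicon {y}"
            )
    mid = seq[template.left_arm : template.left_arm + len(ins)]
    if mid != ins:
        raise TemplateInconsistentError(
            "declared insert not found between the homology arms"
        )
    right_ref = locus.amplicon[right_start : right_start + template.right_arm]
    right_obs = seq[template.left_arm + len(ins) :]
    for i, (x, y) in enumerate(zip(right_obs, right_ref)):
        if x != y:
            raise TemplateInconsistentError(
                f"right arm mismatch at template position "
                f"{template.left_arm + len(ins) + i}: {x} vs amplicon {y}"
            )

    return TemplateReport(
        left_arm=template.left_arm,
        right_arm=template.right_arm,
        insert_len=len(ins),
        deletion_len=template.deletion_len,
        edited_allele=apply_edit(locus.amplicon, cut, ins, template.deletion_len),
    )


def read_fasta(path: str | Path) -> str:
    """Read a single-record FASTA, uppercase-normalised, U->T."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly 1 FASTA record, got {len(records)}")
    return _clean(str(records[0].seq))


def load_locus(spec: dict, base_dir: str | Path = ".") -> tuple[TargetLocus, str]:
    """Build a locus from one config mapping.

    Keys: ``name``, ``protospacer``, ``pam``, ``strand`` (default '+'),
    ``expected_insert`` (amplicon plus-strand frame, optional) and either
    ``amplicon`` (inline sequence) or ``amplicon_fasta`` (path).  Returns the
    locus and the expected insert mapped into window frame.
    """
    if "amplicon" in spec:
        amplicon = spec["amplicon"]
    elif "amplicon_fasta" in spec:
        amplicon = read_fasta(Path(base_dir) / spec["amplicon_fasta"])
    else:
        raise ValueError(f"locus {spec.get('name')}: need 'amplicon' or 'amplicon_fasta'")
    locus = TargetLocus(
        name=spec["name"],
        protospacer=spec["protospacer"],
        pam=spec["pam"],
        amplicon=amplicon,
        strand=spec.get("strand", "+"),
    )
    insert = spec.get("expected_insert", "")
    return locus, insert_in_window_frame(locus, _clean(insert) if insert else "")


def load_locus_config(path: str | Path) -> list[tuple[TargetLocus, str]]:
    """Load a YAML/JSON locus config file (one mapping or a list of them)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if isinstance(data, dict) and "loci" in data:
        data = data["loci"]
    if isinstance(data, dict):
        data = [data]
    return [load_locus(spec, base_dir=path.parent) for spec in data]
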