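"""Capping-peptide candidate specifications.

A candidate inhibitor is a short core sequence threaded onto the zipper
template (α-synuclein author numbering; the NACore template spans 68–78,
the 9-residue design register 69–77), plus per-position modifications
(tryptophan substitution, backbone N-methylation, other substitutions) and
an optional charged solubility/delivery tag (poly-lysine or TAT) on one
terminus. Tags are treated as disordered: they enter scoring only through
net formal charge, never as 3D atoms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from .atoms import AA1_TO_3, FORMAL_CHARGES
from .errors import ValidationError

NACORE_SEQUENCE = "GAVVTGVTAVA"
NACORE_SPAN = (68, 78)
#: The 9-residue design register inside NACore.
CORE9_SPAN = (69, 77)

#: Default tag sequences. The poly-lysine tag defaults to K4. The TAT
#: sequence is an assumption (the common TAT47-57 cell-penetration peptide),
#: NOT taken from the design source, and is configurable.
TAG_SEQUENCES = {
    "none": "",
    "poly_lysine": "KKKK",
    "tat": "YGRKKRRQRRR",
}

MOD_KINDS = ("trp_substitution", "n_methylation", "other_substitution")


def nacore_segment(start: int = CORE9_SPAN[0], end: int = CORE9_SPAN[1]) -> str:
    """Subsequence of NACore by author residue numbers (inclusive)."""
    lo, hi = NACORE_SPAN
    if not (lo <= start <= end <= hi):
        raise ValidationError(
            f"span {start}–{end} outside NACore ({lo}–{hi})"
        )
    return NACORE_SEQUENCE[start - lo : end - lo + 1]


@dataclass(frozen=True)
class Modification:
    """One per-position modification, in author numbering."""

    position: int
    kind: str  # one of MOD_KINDS
    new_residue: str | None = None  # 1-letter, for substitutions

    def __post_init__(self):
        if self.kind not in MOD_KINDS:
            raise ValidationError(f"unknown modification kind {self.kind!r}")
        if self.kind == "trp_substitution":
            object.__setattr__(self, "new_residue", "W")
        if self.kind == "other_substitution":
            if not self.new_residue or self.new_residue not in AA1_TO_3:
                raise ValidationError(
                    f"other_substitution at {self.position} needs a valid "
                    "1-letter residue"
                )


@dataclass(frozen=True)
class CandidateInhibitor:
    """A capping-peptide specification."""

    label: str
    core_sequence: str
    start_position: int = CORE9_SPAN[0]
    modifications: tuple[Modification, ...] = ()
    tag: str = "none"  # none | poly_lysine | tat
    tag_terminus: str = "C"  # N | C
    tag_sequence: str | None = None  # overrides TAG_SEQUENCES
    partially_specified: bool = False

    def __post_init__(self):
        if not (3 <= len(self.core_sequence) <= 15):
            raise ValidationError("core_sequence must be 3–15 residues")
        for letter in self.core_sequence:
            if letter not in AA1_TO_3:
                raise ValidationError(f"unknown residue letter {letter!r}")
        if self.tag not in TAG_SEQUENCES:
            raise ValidationError(f"unknown tag {self.tag!r}")
        if self.tag_terminus not in ("N", "C"):
            raise ValidationError("tag terminus must be N or C")
        lo, hi = self.span
        seen = set()
        for mod in self.modifications:
            if not (lo <= mod.position <= hi):
                raise ValidationError(
                    f"modification position {mod.position} outside the core "
                    f"span {lo}–{hi}"
                )
            if mod.position in seen:
                raise ValidationError(
                    f"multiple modifications at position {mod.position}"
                )
            seen.add(mod.position)
            if (
                mod.kind == "n_methylation"
                and self.residue_at(mod.position) == "P"
            ):
                raise ValidationError(
                    f"position {mod.position} (Pro) has no backbone amide to "
                    "methylate"
                )
        object.__setattr__(self, "modifications", tuple(self.modifications))

    # -- sequence bookkeeping ----------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return (
            self.start_position,
            self.start_position + len(self.core_sequence) - 1,
        )

    def residue_at(self, position: int) -> str:
        lo, hi = self.span
        if not (lo <= position <= hi):
            raise ValidationError(f"position {position} outside span {lo}–{hi}")
        return self.core_sequence[position - lo]

    @property
    def effective_sequence(self) -> str:
        """Core sequence with substitutions applied."""
        seq = list(self.core_sequence)
        lo, _ = self.span
        for mod in self.modifications:
            if mod.new_residue:
                seq[mod.position - lo] = mod.new_residue
        return "".join(seq)

    @property
    def n_methylated_positions(self) -> tuple[int, ...]:
        return tuple(
            m.position
            for m in self.modifications
            if m.kind == "n_methylation"
        )

    @property
    def tag_residues(self) -> str:
        if self.tag == "none":
            return ""
        if self.tag_sequence is not None:
            return self.tag_sequence
        return TAG_SEQUENCES[self.tag]

    def net_charge(self, include_termini: bool = False) -> int:
        """Net formal charge of core + tag (K/R = +1, D/E = −1).

        Termini are uncharged by default: synthetic capping peptides are
        assumed N-acetylated / C-amidated.
        """
        q = sum(
            FORMAL_CHARGES.get(letter, 0)
            for letter in self.effective_sequence + self.tag_residues
        )
        if include_termini:
            q += 0  # +1 (N-term) − 1 (C-term) for free termini
        return q

    def with_substitution(self, position: int, letter: str) -> "CandidateInhibitor":
        """Copy with the residue at ``position`` replaced (design moves)."""
        lo, _ = self.span
        seq = list(self.core_sequence)
        seq[position - lo] = letter
        mods = tuple(m for m in self.modifications if m.position != position)
        return replace(
            self, core_sequence="".join(seq), modifications=mods
        )


# ---------------------------------------------------------------------------
# The four characterized designs
# ---------------------------------------------------------------------------

def reconstruct_paper_candidates(
    tat_sequence: str | None = None,
    poly_lysine_length: int = 4,
    core_span: tuple[int, int] = CORE9_SPAN,
) -> list[CandidateInhibitor]:
    """The four characterized capping inhibitors, as parameterized specs.

    S37: 9-residue core (69–77) with Trp replacing Thr72, C-terminal
    poly-lysine tag. S61/S62: same core and substitution, TAT tag. S71:
    N-methylated Gly73, TAT tag. The designs' full synthesized sequences
    (linkers, exact tag placement for the TAT variants) were never published,
    so every unprinted choice is exposed as an argument and the candidates
    are flagged ``partially_specified``.
    """
    core = nacore_segment(*core_span)
    polyk = "K" * poly_lysine_length
    trp72 = (Modification(72, "trp_substitution"),)
    meth73 = (Modification(73, "n_methylation"),)
    common = dict(
        core_sequence=core,
        start_position=core_span[0],
        partially_specified=True,
    )
    return [
        CandidateInhibitor(
            label="S37", modifications=trp72, tag="poly_lysine",
            tag_terminus="C", tag_sequence=polyk, **common,
        ),
        CandidateInhibitor(
            label="S61", modifications=trp72, tag="tat",
            tag_terminus="C", tag_sequence=tat_sequence, **common,
        ),
        CandidateInhibitor(
            label="S62", modifications=trp72, tag="tat",
            tag_terminus="C", tag_sequence=tat_sequence, **common,
        ),
        CandidateInhibitor(
            label="S71", modifications=meth73, tag="tat",
            tag_terminus="C", tag_sequence=tat_sequence, **common,
        ),
    ]


# ---------------------------------------------------------------------------
# Candidate file format: LABEL<TAB>SEQUENCE<TAB>mods=72W;73mG<TAB>tag=TAT@N
# ---------------------------------------------------------------------------

_MOD_RE = re.compile(r"^(\d+)(m?)([A-Z])$")
_TAG_NAMES = {"TAT": "tat", "POLYK": "poly_lysine", "K4": "poly_lysine"}


def parse_candidate_line(line: str, start_position: int = CORE9_SPAN[0]):
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 2:
        raise ValidationError(f"candidate line needs LABEL<TAB>SEQUENCE: {line!r}")
    label, sequence = fields[0].strip(), fields[1].strip().upper()
    mods: list[Modification] = []
    tag, terminus = "none", "C"
    for extra in fields[2:]:
        extra = extra.strip()
        if extra.startswith("mods="):
            for token in filter(None, extra[5:].split(";")):
                m = _MOD_RE.match(token.strip())
                if not m:
                    raise ValidationError(f"bad modification token {token!r}")
                pos, methyl, letter = int(m.group(1)), m.group(2), m.group(3)
                if methyl:
                    mods.append(Modification(pos, "n_methylation"))
                elif letter == "W":
                    mods.append(Modification(pos, "trp_substitution"))
                else:
                    mods.append(
                        Modification(pos, "other_substitution", letter)
                    )
        elif extra.startswith("tag="):
            spec = extra[4:]
            name, _, term = spec.partition("@")
            key = name.strip().upper()
            if key not in _TAG_NAMES:
                raise ValidationError(f"unknown tag {name!r}")
            tag = _TAG_NAMES[key]
            if term:
                terminus = term.strip().upper()
        elif extra:
            raise ValidationError(f"unknown candidate field {extra!r}")
    return CandidateInhibitor(
        label=label,
        core_sequence=sequence,
        start_position=start_position,
        modifications=tuple(mods),
        tag=tag,
        tag_terminus=terminus,
    )


def read_candidate_file(path, start_position: int = CORE9_SPAN[0]):
    """Read a one-candidate-per-line text file; '#' lines are comments."""
    lines = [
        ln
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ValidationError(f"{path}: no candidates found")
    return [parse_candidate_line(ln, start_position) for ln in lines]


def format_candidate_line(c: CandidateInhibitor) -> str:
    parts = [c.label, c.core_sequence]
    if c.modifications:
        tokens = []
        for m in c.modifications:
            if m.kind == "n_methylation":
                tokens.append(f"{m.position}m{c.residue_at(m.position)}")
            else:
                tokens.append(f"{m.position}{m.new_residue}")
        parts.append("mods=" + ";".join(tokens))
    if c.tag != "none":
        name = "TAT" if c.tag == "tat" else "polyK"
        parts.append(f"tag={name}@{c.tag_terminus}")
    return "\t".join(parts)
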