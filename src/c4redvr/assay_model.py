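"""In-silico model of the paralog-specific C4 exon 29 CT-insertion assay.

The wet assay amplifies an 864 bp fragment of complement *C4* spanning the
paralog-defining exon 26 sequence through the exon 29 CT-insertion site, with
a single FAM label on the reverse primer. The product is digested with PshAI,
a blunt cutter whose degenerate site (GACNN^NNGTC) occurs once inside the
C4A-specific sequence and nowhere in C4B. On a capillary run the labelled
digestion product therefore sizes at 794 bp for C4A and 864 bp for C4B, and
the 2 bp CT insertion shifts either peak by +2 bp (796 / 866 bp).

This module builds synthetic reference amplicons with exactly that geometry,
performs the degenerate-site search and digest, and classifies observed peak
sizes into the four diagnostic channels.

Coordinates are 0-based, half-open; fragment lengths are measured on the
labelled strand. Only the labelled fragment is visible to the sequencer, so
double-strand overhangs are not modelled (PshAI is blunt in any case).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Enzyme",
    "Amplicon",
    "Fragment",
    "PSHAI",
    "PEAK_SIZES",
    "AMPLICON_LENGTH",
    "INSERTION_LENGTH",
    "build_reference_amplicons",
    "find_recognition_sites",
    "digest",
    "classify_peak_size",
    "labeled_fragment",
    "write_amplicons_fasta",
    "read_amplicons_fasta",
]

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Full amplicon length without the insertion (bp).
AMPLICON_LENGTH = 864
#: The CT insertion adds two bases.
INSERTION_LENGTH = 2
#: Labelled-fragment sizes of the four diagnostic channels (bp).
PEAK_SIZES = {"A_wt": 794, "A_ins": 796, "B_wt": 864, "B_ins": 866}

# The labelled (reverse-primer) end is the 3' end of the stored strand; the
# C4A cut must leave a 794 bp labelled product, i.e. the blunt cut sits
# 864 - 794 = 70 bp from the unlabelled end.
_UNLABELED_STUB = AMPLICON_LENGTH - PEAK_SIZES["A_wt"]  # 70


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme with a degenerate recognition site and blunt cut."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError("recognition pattern must be non-empty")
        bad = set(self.recognition.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"non-IUPAC codes in recognition pattern: {sorted(bad)}")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset must lie within the recognition pattern")

    @property
    def regex(self) -> "re.Pattern[str]":
        # Lookahead so overlapping matches are all reported.
        body = "".join(
            c if len(IUPAC_CODES[c]) == 1 else f"[{IUPAC_CODES[c]}]"
            for c in self.recognition.upper()
        )
        return re.compile(f"(?={body})")


#: PshAI: GACNN^NNGTC, blunt cut between the two central N pairs.
PSHAI = Enzyme("PshAI", "GACNNNNGTC", 5)

# C4A hosts the PshAI site so that the cut falls _UNLABELED_STUB bp from the
# 5' (unlabelled) end; C4B carries a different motif at the same coordinates.
SITE_START = _UNLABELED_STUB - PSHAI.cut_offset  # 65
PARALOG_REGION = (SITE_START, SITE_START + len(PSHAI.recognition))  # [65, 75)
_B_PARALOG_BLOCK = "CTGAGTACAT"  # same length, breaks the GAC...GTC core
#: 0-based position at which the duplicated CT is inserted (labelled side of
#: the cut, within the exon-29 portion of the amplicon).
INSERTION_POS = 820


@dataclass(frozen=True)
class Amplicon:
    sequence: str
    paralog: str  # "C4A" | "C4B"
    has_insertion: bool
    labeled_end: str = "3'"  # fluorophore on the reverse-primer side

    def __post_init__(self) -> None:
        if self.paralog not in ("C4A", "C4B"):
            raise ValueError("paralog must be 'C4A' or 'C4B'")
        if self.labeled_end not in ("5'", "3'"):
            raise ValueError("labeled_end must be \"5'\" or \"3'\"")
        expected = AMPLICON_LENGTH + (INSERTION_LENGTH if self.has_insertion else 0)
        if len(self.sequence) != expected:
            raise ValueError(
                f"{self.paralog} amplicon must be {expected} bp, got {len(self.sequence)}"
            )

    @property
    def label(self) -> str:
        return f"{self.paralog}_{'ins' if self.has_insertion else 'wt'}"


@dataclass(frozen=True)
class Fragment:
    length: int
    labeled: bool

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("fragment length must be >= 1")


def find_recognition_sites(sequence: str, enzyme: Enzyme = PSHAI) -> list[int]:
    """Return sorted 0-based start positions of every (possibly overlapping)
    match of the enzyme's degenerate recognition pattern."""
    seq = sequence.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("sequence must contain only A/C/G/T")
    return [m.start() for m in enzyme.regex.finditer(seq)]


def digest(amplicon: Amplicon, enzyme: Enzyme = PSHAI) -> list[Fragment]:
    """Cut the amplicon at every recognition site (+cut_offset) and mark the
    fragment carrying the fluorophore. Zero sites yield one labelled fragment
    spanning the whole amplicon."""
    seq = amplicon.sequence
    cuts = [s + enzyme.cut_offset for s in find_recognition_sites(seq, enzyme)]
    bounds = [0, *cuts, len(seq)]
    labeled_idx = len(bounds) - 2 if amplicon.labeled_end == "3'" else 0
    return [
        Fragment(b - a, labeled=(i == labeled_idx))
        for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]))
    ]


def labeled_fragment(amplicon: Amplicon, enzyme: Enzyme = PSHAI) -> Fragment:
    """The single fragment visible on the capillary trace."""
    (frag,) = [f for f in digest(amplicon, enzyme) if f.labeled]
    return frag


def classify_peak_size(size: float, tolerance: float = 0.9) -> Optional[str]:
    """Assign an observed peak size (bp) to the nearest diagnostic channel
    {A_wt, A_ins, B_wt, B_ins} within ``tolerance``; None if unclassifiable.

    tolerance must stay below 1 bp: the wild-type/insertion channels of each
    paralog are only 2 bp apart.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    if not 0 < tolerance < 1:
        raise ValueError("tolerance must lie in (0, 1) bp")
    label, ref = min(PEAK_SIZES.items(), key=lambda kv: abs(size - kv[1]))
    return label if abs(size - ref) <= tolerance else None


def _assemble(backbone: np.ndarray, a_core: str) -> dict[str, str]:
    lo, hi = PARALOG_REGION
    a = backbone.copy()
    a[lo:hi] = list("GAC" + a_core + "GTC")
    b = backbone.copy()
    b[lo:hi] = list(_B_PARALOG_BLOCK)
    a_wt = "".join(a)
    b_wt = "".join(b)
    ins = lambda s: s[:INSERTION_POS] + "CT" + s[INSERTION_POS:]
    return {"C4A_wt": a_wt, "C4A_ins": ins(a_wt), "C4B_wt": b_wt, "C4B_ins": ins(b_wt)}


def build_reference_amplicons(seed: int, enzyme: Enzyme = PSHAI) -> list[Amplicon]:
    """Construct the four reference amplicons (each paralog x insertion status).

    Sequences are random apart from the constrained features: shared backbone
    (the two paralogs differ only at the paralog-defining region, emulating
    their ~99% homology), one engineered PshAI site in C4A positioned so the
    labelled digestion product is 794 bp (796 bp with the insertion), no site
    anywhere in C4B, and a CT duplication at the insertion position. Spurious
    sites arising by chance are removed by redrawing the offending window
    (rejection sampling), which preserves all engineered features.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    backbone = rng.choice(bases, size=AMPLICON_LENGTH)
    # The insertion duplicates the CT immediately preceding it.
    backbone[INSERTION_POS - 2 : INSERTION_POS] = list("CT")
    a_core = "".join(rng.choice(bases, size=4))

    lo, hi = PARALOG_REGION
    protected = set(range(lo, hi)) | {INSERTION_POS - 2, INSERTION_POS - 1}

    for _ in range(1000):
        seqs = _assemble(backbone, a_core)
        bad: set[int] = set()
        for name, seq in seqs.items():
            expected = {SITE_START} if name.startswith("C4A") else set()
            inserted = name.endswith("ins")
            for s in find_recognition_sites(seq, enzyme):
                if s in expected:
                    continue
                for pos in range(s, s + len(enzyme.recognition)):
                    # Map sequence position back to a backbone coordinate.
                    if inserted and pos >= INSERTION_POS + INSERTION_LENGTH:
                        pos -= INSERTION_LENGTH
                    elif inserted and pos >= INSERTION_POS:
                        continue  # the inserted CT itself is immutable
                    if 0 <= pos < AMPLICON_LENGTH:
                        bad.add(pos)
        redraw = sorted(bad - protected)
        if not bad:
            return [
                Amplicon(seqs["C4A_wt"], "C4A", False),
                Amplicon(seqs["C4A_ins"], "C4A", True),
                Amplicon(seqs["C4B_wt"], "C4B", False),
                Amplicon(seqs["C4B_ins"], "C4B", True),
            ]
        if not redraw:  # spurious site made entirely of protected bases
            raise RuntimeError("cannot remove spurious recognition site")
        backbone[redraw] = rng.choice(bases, size=len(redraw))
    raise RuntimeError("rejection sampling failed to converge")


def write_amplicons_fasta(amplicons: list[Amplicon], path: str) -> None:
    records = [
        SeqRecord(Seq(a.sequence), id=a.label, description="") for a in amplicons
    ]
    SeqIO.write(records, path, "fasta")


def read_amplicons_fasta(path: str) -> list[Amplicon]:
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        paralog, status = rec.id.split("_")
        out.append(Amplicon(str(rec.seq), paralog, status == "ins"))
    return out
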