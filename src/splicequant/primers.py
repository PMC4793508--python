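"""Primer-design quality checks.

Implements the constraint set used to design the four TRPM3 splice-variant
primer pairs: nearest-neighbor melting temperature, GC content 40-60 %, a GC
clamp at the 3' end, bounded self-complementarity (<= 8 nt) and bounded
3'-end complementarity (<= 3 nt), and amplicon size below 210 bp when a
template is supplied.  Genome-wide specificity screening is out of scope.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "PrimerRole",
    "PrimerSpec",
    "NNParams",
    "PrimerConstraints",
    "PrimerReport",
    "TRPM3_PRIMERS",
    "gc_content",
    "gc_clamp",
    "nn_tm",
    "self_complementarity",
    "three_prime_complementarity",
    "amplicon_length",
    "check_primer_set",
    "read_primers",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class PrimerRole(str, enum.Enum):
    FORWARD = "forward"
    REVERSE = "reverse"
    BOUNDARY_SPANNING = "boundary_spanning"


@dataclass(frozen=True)
class PrimerSpec:
    """A primer sequence, written 5'->3'."""

    name: str
    sequence: str
    role: PrimerRole = PrimerRole.FORWARD

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace(" ", "")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 15:
            raise ValueError(
                f"primer {self.name}: length {len(seq)} < 15 nt minimum"
            )
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(
                f"primer {self.name}: invalid characters {sorted(bad)}; "
                f"alphabet is A/C/G/T"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


#: The published TRPM3 primer set: two variant-specific pairs (the
#: boundary-spanning pair for the spliced variant 1 and the pair annealing
#: inside the spliced-out region for variant 2) and two control pairs common
#: to both variants.
TRPM3_PRIMERS: tuple[PrimerSpec, ...] = (
    PrimerSpec("control2_fwd", "TCGCTCGCAGCCAGATCTTTATTTA", PrimerRole.FORWARD),
    PrimerSpec("control2_rev", "GGTACAATGTATTTGAGGGCCCATGTC", PrimerRole.REVERSE),
    PrimerSpec("control1_fwd", "AGCCTGGAACAGAGTTGACATCGC", PrimerRole.FORWARD),
    PrimerSpec("control1_rev", "TCTGTCCAGGACTAGGGCATCCAG", PrimerRole.REVERSE),
    PrimerSpec("plus13_fwd", "GCATGCACCGTTTTCTCACCATC", PrimerRole.FORWARD),
    PrimerSpec("plus13_rev", "GGTACAATGTATTTGAGGGCCCATGTC", PrimerRole.REVERSE),
    PrimerSpec("delta13_fwd", "TGGAACAGAGTTGACATCGCTCG", PrimerRole.BOUNDARY_SPANNING),
    PrimerSpec("delta13_rev", "TGAGGGCCCATGTCTTCCATTTTC", PrimerRole.REVERSE),
)


def gc_content(primer: PrimerSpec) -> float:
    """Percentage of G or C bases in the primer."""
    seq = primer.sequence
    if not seq:
        raise ValueError("empty sequence")
    return 100.0 * sum(b in "GC" for b in seq) / len(seq)


def gc_clamp(primer: PrimerSpec, window: int = 5) -> int:
    """Number of G/C bases among the 3'-terminal ``window`` bases.

    The common tool convention for a "GC clamp"; the exact definition varies
    between tools, so the count is reported rather than hard-asserted.
    """
    return sum(b in "GC" for b in primer.sequence[-window:])


@dataclass(frozen=True)
class NNParams:
    """Nearest-neighbor Tm parameter set (reported with every value).

    Defaults: SantaLucia 1997 unified parameters with 50 mM monovalent salt
    and 300 nM primer, a typical qPCR condition.
    """

    table: str = "DNA_NN3"
    na_mM: float = 50.0
    mg_mM: float = 0.0
    primer_nM: float = 300.0

    def describe(self) -> str:
        return (
            f"nearest-neighbor table {self.table}, Na+ {self.na_mM} mM, "
            f"Mg2+ {self.mg_mM} mM, primer {self.primer_nM} nM"
        )


def nn_tm(primer: PrimerSpec, params: NNParams | None = None) -> float:
    """Nearest-neighbor melting temperature of the primer, in degC."""
    params = params or NNParams()
    table = getattr(_mt, params.table)
    return float(
        _mt.Tm_NN(
            primer.sequence,
            nn_table=table,
            Na=params.na_mM,
            Mg=params.mg_mM,
            dnac1=params.primer_nM,
            dnac2=params.primer_nM,
        )
    )


def self_complementarity(primer: PrimerSpec) -> int:
    """Longest self-complementary stem over all ungapped self-alignments.

    The sequence is slid against its own reverse complement at every offset
    and the longest contiguous stretch of matched base pairs — the stem a
    self-dimer or hairpin could form — is returned.  A perfect palindrome
    scores its full length, poly-A scores 0 (A:A is not a pair).
    """
    seq = primer.sequence
    rc = _revcomp(seq)
    n = len(seq)
    best = 0
    for offset in range(-(n - 1), n):
        run = 0
        for i in range(n):
            j = i + offset
            if 0 <= j < n and seq[i] == rc[j]:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


def three_prime_complementarity(
    a: PrimerSpec, b: PrimerSpec | None = None, window: int = 5
) -> int:
    """Longest complementary run anchored at a 3' end between two primers.

    Considers the 3'-terminal ``window`` bases of each primer against the
    full other sequence in every ungapped alignment; returns the maximum
    contiguous complementary run that includes a 3'-terminal base.  With
    ``b`` omitted the primer is checked against itself (self-dimer at the
    3' end).
    """
    b = b or a

    def anchored_run(query: PrimerSpec, subject: PrimerSpec) -> int:
        # run must end at the query's 3'-terminal base
        tail = query.sequence[-window:]
        srev = _revcomp(subject.sequence)
        best = 0
        for offset in range(-(len(tail) - 1), len(srev)):
            run = 0
            # walk backwards from the 3'-terminal base of the tail
            for k in range(len(tail) - 1, -1, -1):
                j = k + offset
                if 0 <= j < len(srev) and tail[k] == srev[j]:
                    run += 1
                else:
                    break
            best = max(best, run)
        return best

    return max(anchored_run(a, b), anchored_run(b, a))


def amplicon_length(
    forward: PrimerSpec, reverse: PrimerSpec, template: str
) -> int | None:
    """Product size of a primer pair on a template, or None if no site.

    Length is counted inclusively from the 5' end of the forward primer's
    binding site to the 5' end of the reverse primer's site on the template
    (both primer footprints included), the convention under which the
    published product sizes (153/78/109/150/204 bp) are quoted.
    """
    template = template.upper().replace(" ", "")
    fwd_start = template.find(forward.sequence)
    rev_site = _revcomp(reverse.sequence)
    rev_start = template.find(rev_site)
    if fwd_start < 0 or rev_start < 0:
        return None
    end = rev_start + len(rev_site)
    if end <= fwd_start:
        return None
    return end - fwd_start


@dataclass(frozen=True)
class PrimerConstraints:
    """Thresholds of the design constraint set (defaults as published)."""

    tm_target_c: float = 72.0
    tm_tolerance_c: float = 0.6
    gc_min_percent: float = 40.0
    gc_max_percent: float = 60.0
    gc_clamp_min: int = 2
    self_complementarity_max: int = 8
    three_prime_complementarity_max: int = 3
    amplicon_max_bp: int = 210
    check_tm: bool = False  # absolute Tm depends on the NN parameter set


@dataclass(frozen=True)
class PrimerReport:
    """Per-primer measured values and constraint pass/fail map."""

    primer: PrimerSpec
    tm_c: float
    gc_percent: float
    gc_clamp_count: int
    self_complementarity: int
    three_prime_complementarity: int
    amplicon_bp: int | None
    passes: dict[str, bool] = field(default_factory=dict)
    nn_params: str = ""

    @property
    def all_pass(self) -> bool:
        return all(self.passes.values())


def check_primer_set(
    primers: list[PrimerSpec],
    constraints: PrimerConstraints | None = None,
    nn_params: NNParams | None = None,
    template: str | None = None,
    pairs: list[tuple[str, str]] | None = None,
) -> list[PrimerReport]:
    """Evaluate every primer of a set against the design constraints.

    3'-complementarity is taken as each primer's worst value against any
    member of the set (its potential partners in a reaction); ``pairs``
    restricts the amplicon-length check to named (forward, reverse) pairs
    when a ``template`` is given.
    """
    constraints = constraints or PrimerConstraints()
    nn_params = nn_params or NNParams()
    by_name = {p.name: p for p in primers}
    reports = []
    for primer in primers:
        tm = nn_tm(primer, nn_params)
        gc = gc_content(primer)
        clamp = gc_clamp(primer)
        selfc = self_complementarity(primer)
        threep = max(three_prime_complementarity(primer, other) for other in primers)
        amp_bp = None
        if template is not None and pairs is not None:
            for fwd_name, rev_name in pairs:
                if primer.name in (fwd_name, rev_name):
                    amp_bp = amplicon_length(
                        by_name[fwd_name], by_name[rev_name], template
                    )
                    break
        passes = {
            "gc_content": constraints.gc_min_percent <= gc <= constraints.gc_max_percent,
            "gc_clamp": clamp >= constraints.gc_clamp_min,
            "self_complementarity": selfc <= constraints.self_complementarity_max,
            "three_prime_complementarity": threep
            <= constraints.three_prime_complementarity_max,
        }
        if constraints.check_tm:
            passes["tm"] = (
                abs(tm - constraints.tm_target_c) <= constraints.tm_tolerance_c
            )
        if amp_bp is not None:
            passes["amplicon_size"] = amp_bp < constraints.amplicon_max_bp
        reports.append(
            PrimerReport(
                primer=primer,
                tm_c=tm,
                gc_percent=gc,
                gc_clamp_count=clamp,
                self_complementarity=selfc,
                three_prime_complementarity=threep,
                amplicon_bp=amp_bp,
                passes=passes,
                nn_params=nn_params.describe(),
            )
        )
    return reports


def read_primers(path: str | Path) -> list[PrimerSpec]:
    """Read primers from FASTA or a two-column CSV (name, sequence)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    primers: list[PrimerSpec] = []
    if text.lstrip().startswith(">"):
        name = None
        chunks: list[str] = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    primers.append(PrimerSpec(name, "".join(chunks)))
                name = line[1:].split()[0] if len(line) > 1 else None
                if not name:
                    raise ValueError(f"{path}: FASTA header without a name")
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence before first FASTA header")
                chunks.append(line)
        if name is not None:
            primers.append(PrimerSpec(name, "".join(chunks)))
        if not primers:
            raise ValueError(f"{path}: no FASTA records found")
        return primers
    import csv as _csv

    rows = list(_csv.reader(text.splitlines()))
    if not rows:
        raise ValueError(f"{path}: empty primer table")
    start = 1 if rows[0] and rows[0][0].lower() in ("name", "primer") else 0
    for row in rows[start:]:
        if not row or not "".join(row).strip():
            continue
        if len(row) < 2:
            raise ValueError(f"{path}: primer rows need (name, sequence)")
        primers.append(PrimerSpec(row[0].strip(), row[1].strip()))
    if not primers:
        raise ValueError(f"{path}: no primers found")
    return primers
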