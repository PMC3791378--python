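"""DNA segment container and FASTA I/O.

The simulated system is a bacterial DNA segment represented as a plain
string over {A,C,G,T}, with one designated target site (the operator the
cognate transcription factor searches for). 3D organisation of the genome
is deliberately not represented: a molecule's position is a single
left-aligned base-pair coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")
#: bases tolerated on input in addition to ACGT (ambiguity code)
TOLERATED_BASES = frozenset("N")


@dataclass(frozen=True)
class Genome:
    """A DNA segment with a designated target site.

    Parameters
    ----------
    sequence
        Uppercase DNA string over {A,C,G,T} (N tolerated on file input).
    target_start
        0-based left edge of the target site.
    target_width
        Width of the target site in bp (21 for the lacI *O*1 operator).
    topology
        ``"circular"`` (default for synthetic segments; avoids end
        artifacts in the 1D random walk) or ``"linear"``.
    """

    sequence: str
    target_start: int = 0
    target_width: int = 21
    topology: str = "circular"
    name: str = field(default="segment", compare=False)

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear or circular, got {self.topology!r}")
        bad = set(self.sequence) - VALID_BASES - TOLERATED_BASES
        if bad:
            pos = next(i for i, b in enumerate(self.sequence) if b in bad)
            raise ValueError(
                f"invalid base {self.sequence[pos]!r} at position {pos}"
            )
        if not 0 <= self.target_start <= len(self.sequence) - self.target_width:
            raise ValueError(
                f"target [{self.target_start}, +{self.target_width}) does not fit "
                f"in sequence of length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def target_site(self) -> str:
        return self.sequence[self.target_start : self.target_start + self.target_width]

    def n_positions(self, footprint: int) -> int:
        """Number of admissible left-aligned binding positions for a footprint."""
        if footprint < 1 or footprint > self.length:
            raise ValueError(f"footprint {footprint} does not fit on genome")
        return self.length if self.topology == "circular" else self.length - footprint + 1

    def with_target(self, target_start: int, target_width: int = 21) -> "Genome":
        return replace(self, target_start=target_start, target_width=target_width)


def read_fasta(
    path,
    *,
    target_start: int = 0,
    target_width: int = 21,
    topology: str = "linear",
) -> Genome:
    """Read a single-record FASTA file into a :class:`Genome`.

    The sequence is uppercased; characters outside {A,C,G,T,N} are rejected
    with the offending position reported.  Target coordinates are not part
    of the FASTA format and are supplied by the caller (typically from a
    config file).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"no FASTA record found in {path}")
    if len(records) > 1:
        raise ValueError(f"expected a single FASTA record in {path}, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    return Genome(
        sequence=seq,
        target_start=target_start,
        target_width=target_width,
        topology=topology,
        name=rec.id or "segment",
    )


def write_fasta(genome: Genome, path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.name, description="")
    SeqIO.write([rec], str(path), "fasta")


def target_bed_line(genome: Genome) -> str:
    """BED line (0-based half-open) for the target site."""
    return f"{genome.name}\t{genome.target_start}\t{genome.target_start + genome.target_width}\ttarget"
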