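"""Core record containers shared by the I/O and denoising layers."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SequenceRecord:
    """One dereplicated amplicon.

    Parameters
    ----------
    id : str
        Unique sequence label.
    seq : str
        Uppercase DNA over {A, C, G, T}.
    total_reads : int
        Total read count (>= 1).
    sample_reads : dict[str, int]
        Ordered mapping sample name -> non-negative count. Empty for FASTA
        input, where only the total abundance is known.
    rank : int | None
        Position after canonical sorting (reads descending, id ascending);
        assigned by :func:`codonoise.core.canonical_sort`.
    """

    id: str
    seq: str
    total_reads: int
    sample_reads: dict[str, int] = field(default_factory=dict)
    rank: int | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.total_reads < 1:
            raise ValueError(f"record {self.id!r}: total_reads must be >= 1")
        if self.sample_reads:
            s = sum(self.sample_reads.values())
            if s != self.total_reads:
                raise ValueError(
                    f"record {self.id!r}: sample counts sum to {s}, "
                    f"total_reads is {self.total_reads}"
                )
            if any(v < 0 for v in self.sample_reads.values()):
                raise ValueError(f"record {self.id!r}: negative sample count")


@dataclass
class Dataset:
    """A collection of dereplicated amplicons from one input file."""

    records: list[SequenceRecord]
    sample_names: list[str] = field(default_factory=list)
    source_dialect: str = "fasta"  # "fasta" or "csv"

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate record id {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_reads(self) -> int:
        return sum(r.total_reads for r in self.records)
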