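"""Readers and writers for the two input dialects and the result files.

Two input dialects are supported for dereplicated amplicons:

* FASTA with a USEARCH-style abundance annotation in the header
  (``>id;size=N;`` — the key is configurable), sequences optionally wrapped.
* Delimited tables (CSV by default) with one row per unique sequence and
  either a total-count column, per-sample count columns, or both.

Outputs are the ESV table in the input dialect (merged abundances), a
tab-separated merge trace (one row per merged daughter), and a tab-separated
run report.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .records import Dataset, SequenceRecord

if TYPE_CHECKING:  # pragma: no cover
    from .core import DenoiseResult

logger = logging.getLogger(__name__)

_VALID = re.compile(r"^[ACGT]+$")


def _clean_seq(record_id: str, raw: str, on_bad: str) -> str | None:
    seq = str(raw).upper()
    if _VALID.match(seq):
        return seq
    if on_bad == "abort":
        raise ValueError(f"record {record_id!r} contains non-ACGT symbols")
    logger.warning("dropping record %r: non-ACGT symbols", record_id)
    return None


def read_fasta(path: str | Path, size_key: str = "size", on_bad: str = "drop") -> Dataset:
    """Read a size-annotated dereplicated FASTA file.

    Each header must carry ``;<size_key>=N`` (trailing ``;`` optional). Records
    with symbols outside {A,C,G,T} are dropped with a warning (``on_bad="drop"``,
    default) or abort the read (``on_bad="abort"``).
    """
    pat = re.compile(r";" + re.escape(size_key) + r"=(\d+);?")
    records: list[SequenceRecord] = []
    n_parsed = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        n_parsed += 1
        header = entry.description or entry.id
        m = pat.search(header)
        if not m:
            raise ValueError(
                f"header {header!r} lacks a ';{size_key}=N' abundance annotation"
            )
        rid = header[: header.index(";")].split()[0] if ";" in header else entry.id
        seq = _clean_seq(rid, str(entry.seq), on_bad)
        if seq is None:
            continue
        records.append(SequenceRecord(id=rid, seq=seq, total_reads=int(m.group(1))))
    if n_parsed == 0:
        logger.warning("empty FASTA file: %s", path)
    return Dataset(records=records, sample_names=[], source_dialect="fasta")


def read_csv(
    path: str | Path,
    id_col: str = "id",
    seq_col: str = "sequence",
    count_col: str = "count",
    sample_cols: list[str] | str = "auto",
    sep: str = ",",
    on_bad: str = "drop",
) -> Dataset:
    """Read a delimited table of dereplicated amplicons.

    Sample columns are every column not named as id/sequence/count when
    ``sample_cols="auto"``. ``total_reads`` comes from the count column when
    present, otherwise from the row-wise sum of sample columns; if both exist
    they must agree (an ambiguous abundance is a hard error).
    """
    df = pd.read_csv(path, sep=sep, dtype={id_col: str})
    for col in (id_col, seq_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from {path}")
    if sample_cols == "auto":
        samples = [c for c in df.columns if c not in (id_col, seq_col, count_col)]
    else:
        samples = list(sample_cols)
    has_count = count_col in df.columns
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise ValueError(f"duplicate record id {dup!r}")

    records: list[SequenceRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        rid = str(d[id_col])
        seq = _clean_seq(rid, d[seq_col], on_bad)
        if seq is None:
            continue
        per_sample = {s: int(d[s]) for s in samples}
        if has_count:
            total = int(d[count_col])
            if per_sample and total != sum(per_sample.values()):
                raise ValueError(
                    f"record {rid!r}: count column ({total}) disagrees with "
                    f"sample sum ({sum(per_sample.values())})"
                )
        else:
            total = sum(per_sample.values())
        records.append(
            SequenceRecord(id=rid, seq=seq, total_reads=total, sample_reads=per_sample)
        )
    if not records:
        logger.warning("no usable records in %s", path)
    return Dataset(records=records, sample_names=samples, source_dialect="csv")


def write_fasta(records: list[SequenceRecord], path: str | Path, size_key: str = "size") -> None:
    entries = [
        BioSeqRecord(Seq(r.seq), id=f"{r.id};{size_key}={r.total_reads};", description="")
        for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def write_csv(
    records: list[SequenceRecord],
    path: str | Path,
    sample_names: list[str],
    id_col: str = "id",
    seq_col: str = "sequence",
    count_col: str = "count",
    sep: str = ",",
) -> None:
    rows = []
    for r in records:
        row: dict[str, object] = {id_col: r.id, count_col: r.total_reads}
        for s in sample_names:
            row[s] = r.sample_reads.get(s, 0)
        row[seq_col] = r.seq
        rows.append(row)
    cols = [id_col, count_col, *sample_names, seq_col]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)


TRACE_COLUMNS = ["daughter", "mother", "d", "ratio", "skew"]


def write_outputs(result: "DenoiseResult", prefix: str | Path, dialect: str = "fasta") -> dict[str, Path]:
    """Write per-criterion ESV files and merge traces.

    Returns a mapping from a descriptive key (``"<criterion>_esv"`` /
    ``"<criterion>_trace"``) to the path written. ESV files use the requested
    dialect; traces are tab-separated with a fixed header.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for crit in result.criteria:
        esvs = result.esvs[crit]
        if dialect == "fasta":
            p = Path(f"{prefix}_{crit}_esv.fasta")
            write_fasta(esvs, p)
        elif dialect == "csv":
            p = Path(f"{prefix}_{crit}_esv.csv")
            write_csv(esvs, p, result.sample_names)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        paths[f"{crit}_esv"] = p

        tp = Path(f"{prefix}_{crit}_trace.tsv")
        rows = [
            {
                "daughter": t.daughter_id,
                "mother": t.mother_id,
                "d": t.d,
                "ratio": t.ratio,
                "skew": t.skew,
            }
            for t in result.trace[crit]
        ]
        pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(tp, sep="\t", index=False)
        paths[f"{crit}_trace"] = tp
    return paths


def write_run_report(report: dict[str, object], path: str | Path) -> None:
    """Write a two-column (parameter, value) tab-separated run report."""
    df = pd.DataFrame(
        {"parameter": list(report.keys()), "value": [str(v) for v in report.values()]}
    )
    df.to_csv(path, sep="\t", index=False)
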