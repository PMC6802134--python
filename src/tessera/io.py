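"""Sequence input, tetracodon scanning, serialization and run configuration.

The FASTA reader is deliberately strict: it reports malformed headers and
illegal characters with line and column numbers, which is why parsing is
done here rather than delegated to a lenient general-purpose reader.
Writers emit byte-stable output (sorted keys, fixed column order, LF line
endings) so reports can be diffed across runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import yaml

from .symmetry import RNA_ALPHABET, symmetry_class
from .tesserae import is_tessera


@dataclass(frozen=True)
class ScanHit:
    """A 4-base window of a scanned sequence with its tessera annotation."""

    record_id: str
    offset: int          # 0-based start of the window
    frame: int           # 0-3; offset % 4 == frame for non-overlapping scans
    oligo: str
    is_tessera: bool
    generator: Optional[str]
    symmetry: str


@dataclass
class RunConfig:
    """Defaults governing output and scanning; round-trips through YAML."""

    output_format: str = "tsv"        # tsv | json
    alphabet: str = "rna"             # rna | dna
    split6: bool = True
    seed: int = 0
    log_level: str = "INFO"


def load_config(path: Union[str, Path]) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))


def _clean_record(lineno_of: List[Tuple[int, str]], record_id: str) -> str:
    """Validate/normalize a record's sequence lines, reporting line + column."""
    out = []
    for lineno, line in lineno_of:
        for col, ch in enumerate(line, start=1):
            up = ch.upper()
            if up == "T":
                up = "U"
            if up not in RNA_ALPHABET:
                raise ValueError(
                    f"illegal character {ch!r} at line {lineno}, column {col} "
                    f"(record {record_id!r})"
                )
            out.append(up)
    if not out:
        raise ValueError(f"record {record_id!r} has an empty sequence")
    return "".join(out)


def read_sequences(path: Union[str, Path], format: str = "fasta") -> List[Tuple[str, str]]:
    """Read (id, oligo) records from a FASTA or plain-text file.

    Plain files hold a single unnamed sequence; whitespace is ignored.
    Characters outside A, C, G, U, T are rejected with position info.
    """
    path = Path(path)
    text = path.read_text()
    if format == "plain":
        seq = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            for col, ch in enumerate(line.strip(), start=1):
                up = ch.upper()
                if up == "T":
                    up = "U"
                if up not in RNA_ALPHABET:
                    raise ValueError(f"illegal character {ch!r} at line {lineno}, column {col}")
                seq.append(up)
        if not seq:
            raise ValueError(f"no sequence found in {path}")
        return [(path.stem, "".join(seq))]
    if format != "fasta":
        raise ValueError(f"unknown format {format!r}; expected 'fasta' or 'plain'")

    records: List[Tuple[str, str]] = []
    current_id: Optional[str] = None
    current_lines: List[Tuple[int, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if current_id is not None:
                records.append((current_id, _clean_record(current_lines, current_id)))
            header = line[1:].strip()
            if not header:
                raise ValueError(f"malformed FASTA header at line {lineno}: empty id")
            current_id = header.split()[0]
            current_lines = []
        else:
            if current_id is None:
                raise ValueError(
                    f"malformed FASTA at line {lineno}: sequence data before any '>' header"
                )
            current_lines.append((lineno, line))
    if current_id is not None:
        records.append((current_id, _clean_record(current_lines, current_id)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[Tuple[str, str]], path: Union[str, Path], width: int = 60) -> None:
    lines = []
    for rec_id, seq in records:
        lines.append(f">{rec_id}")
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width])
    Path(path).write_text("\n".join(lines) + "\n")


def scan_tetracodons(
    seq: str,
    frames: Sequence[int] = (0,),
    record_id: str = "",
    overlapping: bool = False,
) -> List[ScanHit]:
    """Annotate 4-base windows of a sequence.

    For each frame (0-3), windows start at the frame offset and advance by 4
    (or by 1 with ``overlapping``); short tails are skipped.
    """
    seq = seq.upper().replace("T", "U")
    bad = frozenset(f for f in frames) - {0, 1, 2, 3}
    if bad:
        raise ValueError(f"frames must be in 0-3, got {sorted(bad)}")
    if len(seq) < 4:
        raise ValueError("sequence shorter than one tetracodon")
    step = 1 if overlapping else 4
    hits: List[ScanHit] = []
    for frame in sorted(set(frames)):
        for start in range(frame, len(seq) - 3, step):
            window = seq[start : start + 4]
            ok, gen = is_tessera(window)
            hits.append(
                ScanHit(
                    record_id=record_id,
                    offset=start,
                    frame=frame,
                    oligo=window,
                    is_tessera=ok,
                    generator=gen,
                    symmetry=symmetry_class(window),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Byte-stable serialization

def to_tsv(rows: Iterable[Dict], columns: Sequence[str]) -> str:
    """Rows as a TSV string with a header, LF endings, fixed column order."""
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(_cell(row.get(c)) for c in columns))
    return "\n".join(lines) + "\n"


def _cell(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    if isinstance(v, dict):
        return json.dumps(v, sort_keys=True, separators=(",", ":"))
    return str(v)


def to_json(obj) -> str:
    """Stable JSON text (sorted keys, LF-terminated)."""
    return json.dumps(obj, sort_keys=True, indent=2) + "\n"


def emit(text: str, out: Optional[Union[str, Path]] = None) -> None:
    """Write text to a path or stdout."""
    if out is None:
        import sys

        sys.stdout.write(text)
    else:
        Path(out).write_text(text)
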