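"""File formats, run configuration, and logging glue.

FASTA goes through Biopython; quantification tables are plain TSV
('\\t' separator, '.' decimal, UTF-8, no quoting) with empty cells for
missing intensities. Every table written by the pipeline starts with a
comment line carrying the tool version and a hash of the effective
configuration, so outputs are traceable to the run that made them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .synthetic import ChannelDesign, ProteinRecord, _AA_SET

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _header_line(path: str, protein_id: str, occurrence: int = 1) -> int:
    """Locate the 1-based line number of a FASTA header for error messages."""
    seen = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">") and line[1:].split()[0] == protein_id:
                seen += 1
                if seen == occurrence:
                    return lineno
    return 0


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a multi-FASTA protein database.

    The header token before the first whitespace becomes the protein id;
    sequences are uppercased. Duplicate ids, empty sequences, and
    non-standard residues are rejected with the offending line number.
    """
    path = str(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        pid = rec.id
        seq = str(rec.seq).upper()
        if pid in seen:
            raise ValueError(
                f"{path}:{_header_line(path, pid, occurrence=2)}: "
                f"duplicate protein id {pid!r}"
            )
        seen.add(pid)
        if not seq:
            raise ValueError(
                f"{path}:{_header_line(path, pid)}: record {pid!r} has no sequence"
            )
        bad = set(seq) - _AA_SET
        if bad:
            raise ValueError(
                f"{path}:{_header_line(path, pid)}: record {pid!r} contains "
                f"illegal characters {sorted(bad)}"
            )
        records.append(ProteinRecord(pid, seq, rec.description))
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Quantification tables
# ---------------------------------------------------------------------------

def read_quant_table(path: str | Path, design: ChannelDesign) -> pd.DataFrame:
    """Read a peptide or site intensity TSV, keeping missing cells missing.

    All design channels must be present as columns; intensity columns not
    in the design are warned about and dropped; negative intensities are
    rejected with their row number.
    """
    df = pd.read_csv(str(path), sep="\t", comment="#", dtype={"protein_id": str})
    for ch in design.channel_labels:
        if ch not in df.columns:
            raise ValueError(f"{path}: header lacks design channel {ch!r}")
    known_meta = {
        "peptide_seq", "protein_id", "is_unique", "position", "window",
        "localization_prob",
    }
    extra = [
        c for c in df.columns
        if c not in known_meta and c not in design.channel_labels
    ]
    if extra:
        log.warning("%s: ignoring unknown columns %s", path, extra)
        df = df.drop(columns=extra)
    for ch in design.channel_labels:
        df[ch] = pd.to_numeric(df[ch], errors="raise")
        neg = df.index[df[ch] < 0]
        if len(neg):
            raise ValueError(
                f"{path}: negative intensity in channel {ch!r} at row "
                f"{int(neg[0]) + 2}"  # +2: header line + 1-based
            )
    return df


def write_table(
    df: pd.DataFrame, path: str | Path, config_hash: str = "", float_format: str | None = None
) -> None:
    """Write a TSV with a version/config comment header."""
    with open(path, "w") as fh:
        fh.write(f"# kcrtools {__version__} config={config_hash or 'n/a'}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Flat configuration of a full pipeline run (key=value serializable)."""

    # quantification
    fc_threshold: float = 1.2
    alpha: float = 0.05
    loc_prob_min: float = 0.75
    min_values_per_group: int = 2
    use_pvalue: bool = True
    welch: bool = True
    # motifs
    motif_p_threshold: float = 1e-6
    motif_min_occurrences: int = 20
    motif_max: int = 50
    # conservation
    gap_open: int = -11
    gap_extend: int = -1
    min_rbh_score: float = 50.0
    # synthetic run
    seed: int = 0
    n_proteins: int = 150
    site_fraction: float = 0.05
    noise_sd: float = 0.25
    missing_rate: float = 0.05
    n_species: int = 2
    substitution_rate: float = 0.1
    kcr_keep: float = 0.8
    control_keep: float = 0.5
    # bookkeeping
    out_dir: str = "kcr_run"
    log_level: str = "INFO"

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in types:
                    raise ValueError(f"unknown config key {key!r}")
                current = getattr(defaults, key)
                if isinstance(current, bool):
                    kwargs[key] = value.strip() in ("True", "true", "1")
                else:
                    kwargs[key] = type(current)(value.strip())
        return cls(**kwargs)

    def hash(self) -> str:
        payload = ";".join(
            f"{f.name}={getattr(self, f.name)}" for f in dataclasses.fields(self)
        )
        return hashlib.md5(payload.encode()).hexdigest()[:12]


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
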