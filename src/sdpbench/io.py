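"""File formats and run configuration.

Formats used by the pipeline: aligned FASTA for MSAs, a two-column TSV
(seq_id, year) for publication dates, Newick for trees, a minimal PDB file
(one representative CA atom per residue) plus a plain 1-based binding-residue
list for structures, TSV for all result tables, and YAML for run
configuration.  Structure residue numbering is 1-based (PDB convention); MSA
columns are 0-based internally and 1-based in user-facing tables, as stated
in their headers.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .detectors import ScoreTable, SubfamilyPartition
from .evaluation import StructureModel
from .msa import Alignment, AlignmentError, TimedSequence
from .snapshots import BenchmarkConfig

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# alignments and dates
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file with validation.

    All records must have equal length, unique ids, residues over the 20
    amino-acid letters (uppercased on read) and ``-`` as the only gap symbol.
    """
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    try:
        return Alignment.from_records(records)
    except AlignmentError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_alignment(aln: Alignment, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_dates(path: str | Path) -> dict[str, int]:
    """Read the two-column (seq_id TAB year) publication-date table."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns (seq_id, year)")
    df.columns = ["seq_id", "year"]
    if df["seq_id"].duplicated().any():
        dup = df.loc[df["seq_id"].duplicated(), "seq_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sequence id {dup!r}")
    try:
        years = df["year"].astype(int)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-integer year ({exc})") from exc
    return dict(zip(df["seq_id"], years))


def write_dates(seqs: Sequence[TimedSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tyear\n")
        for s in seqs:
            fh.write(f"{s.seq_id}\t{s.publication_date}\n")


def join_dates(aln: Alignment, dates: dict[str, int]) -> list[TimedSequence]:
    """Attach dates to an alignment; undated members are excluded with a warning."""
    out = []
    missing = []
    for sid, seq in aln:
        if sid in dates:
            out.append(TimedSequence(sid, seq, dates[sid]))
        else:
            missing.append(sid)
    if missing:
        logger.warning(
            "%d sequence(s) without publication date excluded: %s",
            len(missing),
            ", ".join(missing[:5]),
        )
    return out


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def write_structure(structure: StructureModel, pdb_path: str | Path,
                    binding_path: str | Path | None = None) -> None:
    """Write the representative-point model as a minimal PDB (one CA/residue)
    and, optionally, the 1-based binding-residue list."""
    sb = StructureBuilder()
    sb.init_structure("mdl")
    sb.init_model(0)
    sb.init_chain("A")
    sb.init_seg("    ")
    for i, xyz in enumerate(structure.coords, start=1):
        sb.init_residue("ALA", " ", i, " ")
        sb.init_atom("CA", np.asarray(xyz, dtype=float), 0.0, 1.0, " ", " CA ", i, "C")
    io = PDBIO()
    io.set_structure(sb.get_structure())
    io.save(str(pdb_path))
    if binding_path is not None:
        with open(binding_path, "w") as fh:
            fh.write("# binding residues, 1-based, matching the PDB file\n")
            for r in structure.binding_residues:
                fh.write(f"{int(r) + 1}\n")


def read_structure(pdb_path: str | Path, binding_path: str | Path) -> StructureModel:
    """Read a minimal one-atom-per-residue PDB plus its binding-residue list."""
    parser = PDBParser(QUIET=True)
    model = parser.get_structure("mdl", str(pdb_path))[0]
    coords = []
    for chain in model:
        for res in chain:
            atoms = list(res.get_atoms())
            if not atoms:
                continue
            coords.append(atoms[0].get_coord())
    if not coords:
        raise FormatError(f"{pdb_path}: no residues found")
    coords = np.asarray(coords, dtype=float)
    binding = np.zeros(len(coords), dtype=bool)
    with open(binding_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            idx = int(line) - 1
            if not 0 <= idx < len(coords):
                raise FormatError(f"{binding_path}: residue {line} out of range")
            binding[idx] = True
    return StructureModel(
        coords=coords,
        binding_flags=binding,
        column_map={i: i for i in range(len(coords))},
    )


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_score_table(tables: Sequence[ScoreTable], path: str | Path) -> None:
    """One TSV per snapshot: column (1-based), method, score, selected."""
    with open(path, "w") as fh:
        fh.write("# column indices are 1-based\n")
        fh.write("column\tmethod\tscore\tselected\n")
        for t in tables:
            chosen = set(t.selected.tolist())
            for p in range(t.n_columns):
                score = t.scores[p]
                stxt = "NA" if np.isnan(score) else f"{score:.6g}"
                fh.write(f"{p + 1}\t{t.method}\t{stxt}\t{int(p in chosen)}\n")


def write_partition(partition: SubfamilyPartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tcluster\n")
        for sid in sorted(partition.cluster_of):
            fh.write(f"{sid}\t{partition.cluster_of[sid]}\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Complete, reproducible description of one benchmark run."""

    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)
    synthetic: dict = field(default_factory=dict)
    n_families: int = 5
    seed: int = 0
    outdir: str = "sdpbench_out"
    mode: str = "synthetic"  # or "precomputed"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "precomputed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "synthetic" and self.seed is None:
            raise ValueError("seed is mandatory in synthetic mode")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {"benchmark", "synthetic", "n_families", "seed", "outdir", "mode"}
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        bench_raw = raw.get("benchmark", {}) or {}
        bench_fields = {f.name for f in dataclasses.fields(BenchmarkConfig)}
        bad = set(bench_raw) - bench_fields
        if bad:
            raise FormatError(f"{path}: unknown benchmark keys {sorted(bad)}")
        bench = BenchmarkConfig(**bench_raw)
        return cls(
            benchmark=bench,
            synthetic=raw.get("synthetic", {}) or {},
            n_families=int(raw.get("n_families", 5)),
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "sdpbench_out")),
            mode=str(raw.get("mode", "synthetic")),
        )

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "benchmark": dataclasses.asdict(self.benchmark),
            "synthetic": dict(self.synthetic),
            "n_families": self.n_families,
            "seed": self.seed,
            "outdir": self.outdir,
            "mode": self.mode,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
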