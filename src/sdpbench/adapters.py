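"""Adapter hooks for real-data mode.

The tested core of the pipeline consumes ``(aligned sequences, publication
dates, structure, column map)`` directly.  Producing those from live resources
— a BLAST homolog search against a sequence database, an alignment step, a
per-sequence publication-date lookup, a structure-homolog search with
binding-site annotations — is deliberately outside the core: implement these
protocols and feed their outputs to :func:`sdpbench.evaluation.run_benchmark`.

The relevant retrieval thresholds (homolog e-value, structure e-value /
identity / coverage) live in :class:`sdpbench.snapshots.BenchmarkConfig` so a
real-data adapter and the synthetic core share one configuration object.
"""

from __future__ import annotations

from typing import Protocol, Sequence

from .evaluation import StructureModel
from .msa import TimedSequence


class HomologSearchAdapter(Protocol):
    """Retrieve and align dated homologs of a query sequence."""

    def fetch_family(self, query_id: str) -> Sequence[TimedSequence]:
        """Return aligned homologs of the query with publication dates."""
        ...


class StructureMappingAdapter(Protocol):
    """Find a structure homolog and map MSA columns to its residues."""

    def fetch_structure(self, query_id: str) -> StructureModel | None:
        """Return a structure model (with ``column_map`` from the alignment
        of the query to the structure homolog), or None when no homolog
        passes the configured thresholds."""
        ...
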