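"""Run configuration: defaults, file parsing, and the round-tripping echo.

A run is fully described by a :class:`RunConfig`; every randomized step
consumes ``seed``. The config echo written next to every run's outputs
re-parses to an equal RunConfig, so a run can be reproduced from its own
artifacts.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import UsageError


@dataclass
class SpeciesInputs:
    """Paths for one species' inputs."""

    counts_mtx: str = ""
    counts_cells: str = ""
    counts_genes: str = ""
    counts_dense: str = ""  # alternative to the MTX triplet
    cell_meta: str = ""
    annotations: str = ""
    annotation_format: str = "table"  # gaf | table | emapper
    gene_col: str = "gene"
    term_col: str = "go_id"
    evidence_col: str = ""


@dataclass
class RunConfig:
    """All knobs of the pipeline, with the defaults used throughout."""

    obo: str = ""
    species_a: SpeciesInputs = field(default_factory=SpeciesInputs)
    species_b: SpeciesInputs = field(default_factory=SpeciesInputs)
    evidence_set: str = "all"  # all | standard | stringent
    namespace: str = "biological_process"
    relations: tuple[str, ...] = ("is_a",)
    propagate_ancestors: bool = False
    normalize_total: float = 1e4
    clip: float = 10.0
    n_variable_terms: int = 2000
    n_pcs: int = 50
    k_neighbors: int = 20
    resolution: float = 1.0
    alpha: float = 0.05
    min_log2fc: float = 0.0
    min_pct: float = 0.0
    top_n: int = 10
    group_key: str = "cell_type"
    seed: int = 0
    outdir: str = "gocellmap_out"

    def validate(self) -> "RunConfig":
        if self.evidence_set not in ("all", "standard", "stringent"):
            raise UsageError(f"unknown evidence set {self.evidence_set!r}")
        if self.namespace not in (
            "biological_process",
            "molecular_function",
            "cellular_component",
        ):
            raise UsageError(f"unknown namespace {self.namespace!r}")
        if not (0 < self.alpha <= 1):
            raise UsageError("alpha must be in (0, 1]")
        return self

    def to_yaml(self) -> str:
        d = asdict(self)
        d["relations"] = list(self.relations)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise UsageError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("species_a", "species_b"):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = SpeciesInputs(**kwargs[key])
        if "relations" in kwargs:
            kwargs["relations"] = tuple(kwargs["relations"])
        return cls(**kwargs).validate()


def file_checksum(path) -> str:
    """SHA-256 of a file, used to fingerprint the ontology release."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def output_header(version: str, obo_checksum: str, seed: int) -> list[str]:
    """Header lines stamped on every output table."""
    return [
        f"gocellmap {version}",
        f"ontology_sha256={obo_checksum}",
        f"seed={seed}",
    ]
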