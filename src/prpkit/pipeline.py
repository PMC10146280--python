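"""End-to-end orchestration: sequence -> map -> network -> frap.

Consumes an MGF of MS/MS spectra, a FASTA of parent proteins and
(optionally) a FRAP plate CSV; emits plain-text reports (TSV, GraphML)
plus a JSON manifest recording parameters, the seed and input
checksums, so a run is auditable and reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .frap import frap_kinetics, read_plate_csv, results_table
from .mapping import map_peptide, read_fasta
from .networking import build_network, edges_table, export_graphml
from .sequencing import ranking_table, sequence_spectrum
from .spectra import read_mgf

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("prpkit")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    mgf: str | None = None
    fasta: str | None = None
    frap_csv: str | None = None
    output_dir: str = "prpkit_out"
    seed: int = 0
    # stage parameters (instrument-convention defaults)
    precursor_tol_ppm: float = 10.0
    frag_tol_da: float = 0.02
    allow_pglu: bool = True
    max_peptide_len: int = 30
    top_candidates: int = 5
    cosine_min: float = 0.7
    min_matched: int = 3
    max_component: int = 100
    analog_max_delta: float = 300.0
    frap_read_times: tuple[float, ...] = (4.0, 16.0)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "frap_read_times" in raw:
            raw["frap_read_times"] = tuple(raw["frap_read_times"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all applicable stages; returns the manifest dict.

    Outputs in ``cfg.output_dir``: sequences.tsv, fragment_hits.tsv,
    network.graphml, network_edges.tsv, frap.tsv (when a plate is
    given) and manifest.json.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "prpkit_version": __version__,
        "parameters": asdict(cfg),
        "inputs": {},
        "counts": {},
        "outputs": [],
    }

    def _stage(name: str, input_id: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed on {input_id!r}: {exc}") from exc

    spectra = []
    if cfg.mgf:
        manifest["inputs"]["mgf"] = _sha256(Path(cfg.mgf))
        spectra = _stage("read_mgf", cfg.mgf, lambda: read_mgf(cfg.mgf))
        log.info("read %d spectra from %s", len(spectra), cfg.mgf)
        manifest["counts"]["spectra"] = len(spectra)

    proteins = []
    if cfg.fasta:
        manifest["inputs"]["fasta"] = _sha256(Path(cfg.fasta))
        proteins = _stage("read_fasta", cfg.fasta, lambda: read_fasta(cfg.fasta))
        manifest["counts"]["proteins"] = len(proteins)

    if spectra and proteins:
        seq_lines: list[str] = []
        hit_lines = ["spectrum\tpeptide\tprotein\tstart\tend\tequivalences"]
        n_candidates = 0
        for s in spectra:
            ranked = _stage(
                "sequence", s.id,
                lambda s=s: sequence_spectrum(
                    s, proteins,
                    tol_ppm=cfg.precursor_tol_ppm,
                    frag_tol_da=cfg.frag_tol_da,
                    allow_pglu=cfg.allow_pglu,
                    max_len=cfg.max_peptide_len,
                    top=cfg.top_candidates,
                ),
            )
            n_candidates += len(ranked)
            table = ranking_table(s.id, ranked)
            seq_lines.extend(table.splitlines()[0 if not seq_lines else 1:])
            if ranked:
                best = ranked[0]
                for prot in proteins:
                    for hit in map_peptide(best.peptide, prot):
                        hit_lines.append(
                            f"{s.id}\t{best.peptide.to_dashed()}\t{hit.protein_id}"
                            f"\t{hit.start}\t{hit.end}\t"
                            f"{','.join(sorted(hit.equivalences_used)) or '-'}"
                        )
        (out / "sequences.tsv").write_text("\n".join(seq_lines) + "\n")
        (out / "fragment_hits.tsv").write_text("\n".join(hit_lines) + "\n")
        manifest["counts"]["ranked_candidates"] = n_candidates
        manifest["outputs"] += ["sequences.tsv", "fragment_hits.tsv"]
        log.info("sequenced %d spectra (%d ranked candidates)",
                 len(spectra), n_candidates)

    if spectra:
        net = _stage("network", cfg.mgf or "spectra",
                     lambda: build_network(
                         spectra,
                         cosine_min=cfg.cosine_min,
                         min_matched=cfg.min_matched,
                         frag_tol=cfg.frag_tol_da,
                         max_component=cfg.max_component,
                         analog_max_delta=cfg.analog_max_delta,
                     ))
        export_graphml(net, out / "network.graphml")
        (out / "network_edges.tsv").write_text(edges_table(net))
        manifest["counts"]["network_edges"] = len(net.edges)
        manifest["outputs"] += ["network.graphml", "network_edges.tsv"]
        log.info("network: %d nodes, %d edges kept",
                 len(net.nodes), len(net.edges))

    if cfg.frap_csv:
        manifest["inputs"]["frap_csv"] = _sha256(Path(cfg.frap_csv))
        plate = _stage("read_plate", cfg.frap_csv,
                       lambda: read_plate_csv(cfg.frap_csv))
        results = _stage("frap", cfg.frap_csv,
                         lambda: frap_kinetics(plate, cfg.frap_read_times))
        (out / "frap.tsv").write_text(results_table(results))
        manifest["counts"]["frap_results"] = len(results)
        manifest["outputs"].append("frap.tsv")
        log.info("FRAP: %d sample/time results", len(results))

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["outputs"].append("manifest.json")
    return manifest
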