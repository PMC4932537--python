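"""End-to-end workflow: actives -> conformers -> features -> consensus
model -> library screen, with deterministic artifacts.

Artifacts (``model.json``, ``hits.tsv``) are written atomically
(temp file + rename) and reruns with the same configuration produce
byte-identical outputs.  The run log goes to stderr and records the
serialized configuration, its hash and the seed.
"""

from __future__ import annotations

import hashlib
import json
import os
import sys
import tempfile
from dataclasses import asdict, dataclass, field, replace
from typing import Callable, Sequence

from . import __version__
from .chem import Molecule, read_library
from .conformers import EnsembleConfig, generate_ensemble
from .elucidate import ElucidationResult, elucidate
from .features import perceive_features
from .screen import ScreenReport, screen_library


@dataclass(frozen=True)
class PipelineConfig:
    """Merged run configuration (CLI flag > config file > default)."""

    actives_path: str
    library_path: str | None = None
    outdir: str = "out"
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    tau: float = 1.0
    min_coverage: float = 0.7
    planarity_max: float = 0.75
    seed: int = 0

    def serialized(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.serialized().encode()).hexdigest()[:16]


def load_config_file(path: str) -> dict:
    """Key-value config file: one ``key = value`` per line, # comments."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {raw.strip()!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            out[key] = value
    return out


def _atomic_write(path: str, writer: Callable[[str], None]) -> None:
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def prepare_entries(mols: Sequence[Molecule], cfg: PipelineConfig):
    """Ensembles + perceived features for a list of molecules.

    Each molecule gets its own seed derived from the run seed and its
    position, so entry order is reproducible and molecules are
    independent.
    """
    entries = []
    for i, mol in enumerate(mols):
        derived = (cfg.seed * 1000003 + i) % (2**31 - 1)
        ecfg = replace(cfg.ensemble, seed=derived)
        ensemble = generate_ensemble(mol, ecfg)
        entries.append((mol.id, [perceive_features(c) for c in ensemble]))
    return entries


def run_pipeline(cfg: PipelineConfig, log=None):
    """Run elucidation (and, if a library is given, screening).

    Returns ``(ElucidationResult, ScreenReport | None)`` and writes
    ``model.json`` (and ``hits.tsv``) under ``cfg.outdir``.
    """
    log = log or sys.stderr
    print(
        f"phoregen {__version__} | seed={cfg.seed} | "
        f"config_hash={cfg.config_hash()}",
        file=log,
    )
    print(f"config: {cfg.serialized()}", file=log)

    os.makedirs(cfg.outdir, exist_ok=True)
    actives = read_library(cfg.actives_path, _guess_format(cfg.actives_path))
    print(f"actives: {len(actives)} molecules from {cfg.actives_path}", file=log)

    active_entries = prepare_entries(actives, cfg)
    result: ElucidationResult = elucidate(
        active_entries,
        tau=cfg.tau,
        min_coverage=cfg.min_coverage,
        planarity_max=cfg.planarity_max,
    )
    model_path = os.path.join(cfg.outdir, "model.json")
    _atomic_write(model_path, lambda p: result.model.to_json(p) and None)
    print(
        f"model: coverage={result.coverage:.3f} "
        f"cluster_size={result.cluster_size} -> {model_path}",
        file=log,
    )

    report: ScreenReport | None = None
    if cfg.library_path:
        library = read_library(cfg.library_path, _guess_format(cfg.library_path))
        lib_entries = prepare_entries(library, cfg)
        report = screen_library(result.model, lib_entries)
        hits_path = os.path.join(cfg.outdir, "hits.tsv")
        _atomic_write(hits_path, report.to_tsv)
        print(
            f"screen: {len(report.hits)}/{len(report.rows)} hits -> {hits_path}",
            file=log,
        )
    return result, report


def _guess_format(path: str) -> str:
    return "sdf" if path.lower().endswith(".sdf") else "smiles"


def elucidate_fixture_series(
    seed: int = 0,
    conformation_limit: int = 50,
    tau: float = 1.0,
    min_coverage: float = 0.7,
    planarity_max: float = 0.75,
):
    """Elucidate the consensus model of the 16-compound inhibitor series.

    The conformer cap defaults to 50 per molecule (a scaled-down
    ensemble; all other sampling settings are the defaults), which keeps
    the full run in the minutes range on one core.  Returns
    ``(ElucidationResult, entries)`` where ``entries`` are the perceived
    per-conformer feature lists, reusable for cluster diagnostics or
    screening.
    """
    from .data import fixture_molecules

    cfg = PipelineConfig(
        actives_path="",
        ensemble=EnsembleConfig(conformation_limit=conformation_limit),
        tau=tau,
        min_coverage=min_coverage,
        planarity_max=planarity_max,
        seed=seed,
    )
    entries = prepare_entries(fixture_molecules(), cfg)
    result = elucidate(
        entries, tau=tau, min_coverage=min_coverage, planarity_max=planarity_max
    )
    return result, entries
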