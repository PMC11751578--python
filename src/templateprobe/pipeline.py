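"""Experiment orchestration: perturb -> (optional external predictor) -> evaluate.

A run takes targets (structure files or synthetic fixture specs), applies a
list of perturbations, optionally hands each perturbed template to an
external predictor through a subprocess adapter, and scores every stage
against the unperturbed target with the full metric suite.  External
predictors are never bundled: without an adapter the run simply stops at
stage "perturbed".
"""
from __future__ import annotations

import json
import logging
import shlex
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .align import ResidueMapping, map_structures
from .errors import MetricUndefinedError, ParameterError, TemplateProbeError
from .local_metrics import LDDTParams, chi_mae, lddt, stereochemistry_check
from .perturb import PerturbationSpec
from .structio import Structure, extract_sequence, read_structure, standardize, \
    write_fasta, write_structure
from .superpose import all_atom_rmsd, alpha_rmsd, tm_score
from .synthetic import BackboneSpec, RotamerSpec, attach_sidechains, \
    make_backbone, make_globule

logger = logging.getLogger("templateprobe.pipeline")

METRIC_COLUMNS = [
    "tm", "rmsd_all", "rmsd_sidechain", "alpha_rmsd", "lddt_global",
    "chi_mae_overall", "chi_mae_1", "chi_mae_2", "chi_mae_3", "chi_mae_4",
    "n_skipped_atoms", "stereo_violation_fraction",
]


class AdapterError(TemplateProbeError):
    """The external predictor adapter failed or produced unusable output."""


@dataclass
class ExperimentConfig:
    """One experiment grid: targets x perturbations (+ optional predictor).

    ``targets`` entries are either structure file paths (str) or fixture
    specs (dict with ``kind``: "globule" or "backbone" and their
    parameters).  ``predictor`` is a shell command template with
    ``{template}``, ``{sequence}`` and ``{workdir}`` placeholders.
    """

    targets: list = field(default_factory=list)
    perturbations: list[PerturbationSpec] = field(default_factory=list)
    output_dir: str = "runs"
    seed: int = 0
    predictor: str | None = None
    predictor_timeout: float = 900.0
    lddt_params: LDDTParams = field(default_factory=LDDTParams)
    alpha_cap: float = 5.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        perturbations = [PerturbationSpec(**p) for p in raw.get("perturbations", [])]
        lddt_params = LDDTParams(**raw.get("lddt", {}))
        cfg = cls(
            targets=raw.get("targets", []),
            perturbations=perturbations,
            output_dir=raw.get("output_dir", "runs"),
            seed=int(raw.get("seed", 0)),
            predictor=raw.get("predictor"),
            predictor_timeout=float(raw.get("predictor_timeout", 900.0)),
            lddt_params=lddt_params,
            alpha_cap=float(raw.get("alpha_cap", 5.0)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.targets:
            raise ParameterError("config lists no targets")
        if not self.perturbations:
            raise ParameterError("config lists no perturbations")
        for t in self.targets:
            if isinstance(t, str) and not Path(t).exists():
                raise ParameterError(f"target path does not exist: {t}")


# ------------------------------------------------------------------ targets

def load_target(entry, seed: int = 0) -> tuple[str, Structure]:
    """Materialize one target entry: a file path or a fixture spec."""
    if isinstance(entry, str):
        s = standardize(read_structure(entry))
        return Path(entry).stem, s
    if not isinstance(entry, dict):
        raise ParameterError(f"unrecognized target entry {entry!r}")
    spec = dict(entry)
    kind = spec.pop("kind", "globule")
    spec.setdefault("seed", seed)
    if kind == "globule":
        length = int(spec.get("length", 150))
        s = make_globule(length, seed=int(spec["seed"]))
        return f"globule-L{length}-s{spec['seed']}", s
    if kind == "backbone":
        bspec = BackboneSpec(
            length=int(spec.get("length", 100)),
            torsion_profile=spec.get("preset", "mixed"),
            seed=int(spec["seed"]))
        s = make_backbone(bspec)
        if spec.get("sidechains", True):
            s = attach_sidechains(s, RotamerSpec("ideal_single", int(spec["seed"])))
        return f"backbone-{spec.get('preset', 'mixed')}-L{bspec.length}-s{spec['seed']}", s
    raise ParameterError(f"unknown fixture kind {kind!r}")


# --------------------------------------------------------------- evaluation

def evaluate_pair(ref: Structure, model: Structure,
                  mapping: ResidueMapping | None = None,
                  lddt_params: LDDTParams | None = None,
                  alpha_cap: float = 5.0) -> dict:
    """Full metric row for one (reference, model) pair.

    Metrics that are undefined for the pair (e.g. chi-MAE against a
    backbone-only template) are reported as None, never as zero.
    """
    if mapping is None:
        mapping = map_structures(ref, model)
    row: dict = {c: None for c in METRIC_COLUMNS}
    try:
        row["tm"] = tm_score(ref, model, mapping)
    except MetricUndefinedError:
        pass
    try:
        row["alpha_rmsd"] = alpha_rmsd(ref, model, mapping, cap=alpha_cap)
    except MetricUndefinedError:
        pass
    try:
        rep = all_atom_rmsd(ref, model, mapping, atom_set="all")
        row["rmsd_all"] = rep.rmsd
        row["n_skipped_atoms"] = rep.n_skipped
    except MetricUndefinedError:
        pass
    try:
        row["rmsd_sidechain"] = all_atom_rmsd(ref, model, mapping,
                                              atom_set="sidechain").rmsd
    except MetricUndefinedError:
        pass
    try:
        res = lddt(ref, model, mapping, lddt_params)
        row["lddt_global"] = res.global_score
    except MetricUndefinedError:
        pass
    try:
        chi = chi_mae(ref, model, mapping)
        row["chi_mae_overall"] = chi.overall
        for k in range(1, 5):
            row[f"chi_mae_{k}"] = chi.per_index.get(k)
    except MetricUndefinedError:
        pass
    n = model.n_residues
    row["stereo_violation_fraction"] = (
        len(stereochemistry_check(model)) / n if n else None)
    return row


# ----------------------------------------------------------------- adapter

def predictor_adapter(command: str, template_path: Path, sequence_path: Path,
                      workdir: Path, timeout: float = 900.0,
                      min_coverage: float = 0.5) -> Path:
    """Run an external predictor and return its single output structure.

    ``command`` is a shell command template; ``{template}``, ``{sequence}``
    and ``{workdir}`` are substituted before execution.  The adapter must
    deposit exactly one new PDB/mmCIF file under ``workdir``.  The file
    must parse and cover at least ``min_coverage`` of the template's
    residues, else :class:`AdapterError` is raised.
    """
    workdir.mkdir(parents=True, exist_ok=True)
    before = set(workdir.glob("*"))
    cmd = command.format(template=template_path, sequence=sequence_path,
                         workdir=workdir)
    try:
        proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True,
                              timeout=timeout)
    except subprocess.TimeoutExpired as exc:
        raise AdapterError(f"predictor timed out after {timeout}s") from exc
    if proc.returncode != 0:
        raise AdapterError(
            f"predictor exited {proc.returncode}: {proc.stderr.strip()[:500]}")
    candidates = [p for p in workdir.glob("*")
                  if p not in before and p.suffix.lower() in (".pdb", ".cif", ".mmcif")]
    if len(candidates) != 1:
        raise AdapterError(
            f"expected exactly one new structure file in {workdir}, found "
            f"{len(candidates)}")
    out_path = candidates[0]
    try:
        model = read_structure(out_path)
    except TemplateProbeError as exc:
        raise AdapterError(f"predictor output unreadable: {exc}") from exc
    template = read_structure(template_path)
    if model.n_residues < min_coverage * template.n_residues:
        raise AdapterError(
            f"predictor output covers {model.n_residues}/{template.n_residues} "
            f"residues (< {min_coverage:.0%})")
    return out_path


# --------------------------------------------------------------------- run

def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Execute the full grid and write per-row CSV plus aggregate JSON.

    For each target x perturbation the perturbed template is written and
    evaluated (stage "perturbed"); with a predictor configured its output
    is evaluated as stage "refined".  Failures mark the row with a status
    message and the run continues.  Fully reproducible given config.seed.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    log_path = out_dir / "rows.jsonl"
    with open(log_path, "w") as log_fh:
        for t_index, entry in enumerate(config.targets):
            target_id, ref = load_target(entry, seed=config.seed + t_index)
            target_dir = out_dir / target_id
            target_dir.mkdir(exist_ok=True)
            seq_path = target_dir / "sequence.fasta"
            write_fasta(extract_sequence(ref), seq_path)
            write_structure(ref, target_dir / "reference.pdb", format="pdb")
            for p_index, pert in enumerate(config.perturbations):
                # every draw traceable to (global seed, target, perturbation)
                local_seed = int(np.random.SeedSequence(
                    [config.seed, t_index, p_index]).generate_state(1)[0] % (2**31))
                spec = PerturbationSpec(
                    kind=pert.kind, sigma=pert.sigma,
                    n_components=pert.n_components, cbeta_mode=pert.cbeta_mode,
                    cbeta_source=pert.cbeta_source, seed=local_seed)
                perturbed = spec.apply(ref)
                template_path = target_dir / f"perturbed_{p_index}.pdb"
                write_structure(perturbed, template_path, format="pdb")
                base = {"target": target_id, "perturbation": spec.label}
                row = dict(base, stage="perturbed", status="ok",
                           **evaluate_pair(ref, perturbed,
                                           lddt_params=config.lddt_params,
                                           alpha_cap=config.alpha_cap))
                rows.append(row)
                log_fh.write(json.dumps(row, default=float) + "\n")
                if config.predictor:
                    workdir = target_dir / f"refined_{p_index}"
                    try:
                        model_path = predictor_adapter(
                            config.predictor, template_path, seq_path, workdir,
                            timeout=config.predictor_timeout)
                        refined = standardize(read_structure(model_path))
                        row = dict(base, stage="refined", status="ok",
                                   **evaluate_pair(ref, refined,
                                                   lddt_params=config.lddt_params,
                                                   alpha_cap=config.alpha_cap))
                    except AdapterError as exc:
                        logger.warning("adapter failed for %s/%s: %s",
                                       target_id, spec.label, exc)
                        row = dict(base, stage="refined", status=f"failed: {exc}",
                                   **{c: None for c in METRIC_COLUMNS})
                    rows.append(row)
                    log_fh.write(json.dumps(row, default=float) + "\n")
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "metrics.csv", index=False)
    summary = aggregate(table)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return table


def aggregate(table: pd.DataFrame) -> dict:
    """Mean and standard deviation per (perturbation, stage) over ok rows."""
    out: dict = {}
    ok = table[table["status"] == "ok"]
    for (pert, stage), group in ok.groupby(["perturbation", "stage"]):
        entry = {}
        for col in METRIC_COLUMNS:
            values = pd.to_numeric(group[col], errors="coerce").dropna()
            if len(values):
                entry[col] = {"mean": float(values.mean()),
                              "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
                              "n": int(len(values))}
        out[f"{pert}|{stage}"] = entry
    return out
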