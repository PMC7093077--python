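"""Synthetic compartmental chain models and artificial datasets.

The generator emulates the architecture of a two-compartment
biotransformation network: per metabolite pair an extracellular and an
intracellular species, first-order import scaled by an unbound fraction,
first-order export, and Michaelis–Menten conversion of each intracellular
metabolite into the next.  True parameter values are drawn log-uniformly
inside transport/fraction/Vmax boxes of the scales used in the estimation
study ([1e-6, 0.1], [1e-6, 1], [1e-6, 100]) so every fixture is a solvable
recovery problem with a known ground truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from . import expr as ex
from .dataio import (
    ColumnMapping,
    DataSet,
    EstimationProblem,
    ParameterSpec,
    write_trajectory_csv,
)
from .model import (
    Compartment,
    ModelDocument,
    Parameter,
    Reaction,
    Species,
    SpeciesRef,
)
from .quality import QualitySpec
from .sbmlio import write_sbml
from .solvers import SolverSettings, integrate
from .compile import compile_system

__all__ = [
    "TRANSPORT_BOX",
    "FRACTION_BOX",
    "VMAX_BOX",
    "ChainModelSpec",
    "StudyFixture",
    "generate_chain_model",
    "make_artificial_dataset",
    "make_study_fixture",
    "make_nonidentifiable_fixture",
    "write_fixture",
]

# search boxes by parameter class (init interval == search interval)
TRANSPORT_BOX = (1e-6, 0.1)
FRACTION_BOX = (1e-6, 1.0)
VMAX_BOX = (1e-6, 100.0)

# true values are drawn log-uniformly from these sub-ranges, keeping them
# strictly inside the search boxes and dynamically informative
_TRUE_IMPORT = (0.01, 0.08)
_TRUE_EXPORT = (0.005, 0.05)
_TRUE_FU = (0.3, 0.9)
_TRUE_VMAX = (0.5, 20.0)
_TRUE_KM = (20.0, 80.0)

_DEFAULT_T_END = 120.0
_DEFAULT_N_TIMES = 12
_MEDIUM_SIZE = 1.0
_CELL_SIZE = 0.5
_INITIAL_SUBSTRATE = 100.0


@dataclass
class ChainModelSpec:
    n_pairs: int = 3
    seed: int = 0
    initial_substrate: float = _INITIAL_SUBSTRATE

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("need at least one metabolite pair")


@dataclass
class StudyFixture:
    model: ModelDocument  # fitted parameter values deleted
    data: DataSet
    parameters: list[ParameterSpec]
    truth: dict[str, float]
    seed: int
    times: np.ndarray = field(default_factory=lambda: np.array([]))

    def mapping(self) -> ColumnMapping:
        return ColumnMapping({c: c for c in self.data.columns})

    def solver_settings(self) -> SolverSettings:
        return SolverSettings(
            method="rosenbrock", abs_tol=1e-12, rel_tol=1e-6,
            t_start=0.0, t_end=float(self.data.times[-1]),
            output_step=float(self.data.times[-1]) / 100.0)

    def problem(self) -> EstimationProblem:
        return EstimationProblem(
            model=self.model,
            data=self.data,
            mapping=self.mapping(),
            parameters=self.parameters,
            quality=QualitySpec("relative_squared_error"),
            solver=self.solver_settings(),
        )


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_chain_model(
    spec: ChainModelSpec,
) -> tuple[ModelDocument, dict[str, float]]:
    """Build the two-compartment chain model and its true parameter record.

    Per pair ``i``: species ``M{i}_out`` (medium) and ``M{i}_in`` (cell),
    an import reaction ``Import_M{i}_k * fu_M{i} * [M{i}_out]`` and an
    export reaction ``Export_M{i}_k * [M{i}_in]``; per adjacent pair a
    Michaelis–Menten conversion ``M{i}_in -> M{i+1}_in``.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    doc = ModelDocument(model_id=f"chain{spec.n_pairs}")
    doc.compartments.append(Compartment("medium", _MEDIUM_SIZE))
    doc.compartments.append(Compartment("cell", _CELL_SIZE))

    truth: dict[str, float] = {}

    def add_param(pid: str, value: float) -> None:
        doc.parameters.append(Parameter(pid, value=value, constant=True))
        truth[pid] = value

    for i in range(1, spec.n_pairs + 1):
        doc.species.append(Species(
            f"M{i}_out", "medium",
            initial_amount=spec.initial_substrate if i == 1 else 0.0))
        doc.species.append(Species(f"M{i}_in", "cell", initial_amount=0.0))

    for i in range(1, spec.n_pairs + 1):
        add_param(f"Import_M{i}_k", _loguniform(rng, *_TRUE_IMPORT))
        add_param(f"Export_M{i}_k", _loguniform(rng, *_TRUE_EXPORT))
        add_param(f"fu_M{i}", _loguniform(rng, *_TRUE_FU))
    for i in range(1, spec.n_pairs):
        add_param(f"Conv_M{i}M{i + 1}_Vmax", _loguniform(rng, *_TRUE_VMAX))
        add_param(f"Conv_M{i}M{i + 1}_Km", _loguniform(rng, *_TRUE_KM))
    n = spec.n_pairs
    add_param(f"Clear_M{n}_Vmax", _loguniform(rng, *_TRUE_VMAX))
    add_param(f"Clear_M{n}_Km", _loguniform(rng, *_TRUE_KM))

    for i in range(1, spec.n_pairs + 1):
        doc.reactions.append(Reaction(
            id=f"Import_M{i}",
            reactants=[SpeciesRef(f"M{i}_out")],
            products=[SpeciesRef(f"M{i}_in")],
            kinetic_law=ex.parse_infix(
                f"Import_M{i}_k * fu_M{i} * M{i}_out"),
            reversible=False,
        ))
        doc.reactions.append(Reaction(
            id=f"Export_M{i}",
            reactants=[SpeciesRef(f"M{i}_in")],
            products=[SpeciesRef(f"M{i}_out")],
            kinetic_law=ex.parse_infix(f"Export_M{i}_k * M{i}_in"),
            reversible=False,
        ))
    for i in range(1, spec.n_pairs):
        doc.reactions.append(Reaction(
            id=f"Conv_M{i}M{i + 1}",
            reactants=[SpeciesRef(f"M{i}_in")],
            products=[SpeciesRef(f"M{i + 1}_in")],
            kinetic_law=ex.parse_infix(
                f"Conv_M{i}M{i + 1}_Vmax * M{i}_in"
                f" / (Conv_M{i}M{i + 1}_Km + M{i}_in)"),
            reversible=False,
        ))
    # terminal enzymatic clearance of the last intracellular metabolite
    doc.reactions.append(Reaction(
        id=f"Clear_M{n}",
        reactants=[SpeciesRef(f"M{n}_in")],
        kinetic_law=ex.parse_infix(
            f"Clear_M{n}_Vmax * M{n}_in / (Clear_M{n}_Km + M{n}_in)"),
        reversible=False,
    ))
    return doc, truth


def default_times(t_end: float = _DEFAULT_T_END,
                  n: int = _DEFAULT_N_TIMES) -> np.ndarray:
    """Log-spaced sampling grid over the simulation span."""
    return np.geomspace(t_end / 100.0, t_end, n)


def make_artificial_dataset(
    model: ModelDocument,
    truth: dict[str, float],
    times: np.ndarray,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> DataSet:
    """Simulate with the true parameters and sample the requested times.

    With ``noise_cv > 0`` each sampled value is multiplied by
    ``1 + noise_cv * N(0, 1)`` (seeded).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    times = np.asarray(times, dtype=float)
    sys = compile_system(model)
    settings = SolverSettings(
        method="rosenbrock", abs_tol=1e-12, rel_tol=1e-6,
        t_start=0.0, t_end=float(times[-1]), output_times=times)
    traj = integrate(sys, settings, overrides=truth)
    if not traj.ok:
        raise RuntimeError(
            f"artificial-data simulation failed: {traj.failure_reason}")
    species_ids = [s.id for s in model.species]
    cols: dict[str, np.ndarray] = {}
    rng = np.random.Generator(np.random.PCG64(seed))
    for sid in species_ids:
        vals = traj.column(sid).copy()
        if noise_cv > 0:
            vals = vals * (1.0 + noise_cv * rng.standard_normal(len(vals)))
        cols[sid] = vals
    return DataSet(times=times, columns=cols, source="<artificial>")


def _default_fit_targets(n_pairs: int) -> list[str]:
    """Five structurally identifiable targets (fewer for tiny chains)."""
    candidates = ["Import_M1_k", "Export_M1_k"]
    for i in range(1, n_pairs):
        candidates.append(f"Conv_M{i}M{i + 1}_Vmax")
    for i in range(2, n_pairs + 1):
        candidates.append(f"Export_M{i}_k")
    for i in range(2, n_pairs + 1):
        candidates.append(f"Import_M{i}_k")
    return candidates[:5]


def _box_for(pid: str) -> tuple[float, float]:
    if pid.endswith("_Vmax") or pid.endswith("_Km"):
        return VMAX_BOX
    if pid.startswith("fu_"):
        return FRACTION_BOX
    return TRANSPORT_BOX


def _spec_for(pid: str) -> ParameterSpec:
    lo, hi = _box_for(pid)
    return ParameterSpec(pid, lo, hi, lo, hi)  # init interval == search interval


def _delete_parameters(model: ModelDocument, targets: list[str]) -> None:
    for p in model.parameters:
        if p.id in targets:
            p.value = None


def make_study_fixture(
    spec: ChainModelSpec,
    times: np.ndarray | None = None,
    noise_cv: float = 0.0,
    fit_targets: list[str] | None = None,
) -> StudyFixture:
    """Model with deleted parameter values + artificial dataset + range
    specs whose initialization interval equals the search interval."""
    model, truth = generate_chain_model(spec)
    if times is None:
        times = default_times()
    data = make_artificial_dataset(model, truth, times, noise_cv,
                                   seed=spec.seed + 10_000)
    targets = fit_targets if fit_targets is not None \
        else _default_fit_targets(spec.n_pairs)
    unknown = [t for t in targets if t not in truth]
    if unknown:
        raise ValueError(f"fit targets not in model: {unknown}")
    _delete_parameters(model, targets)
    return StudyFixture(
        model=model,
        data=data,
        parameters=[_spec_for(t) for t in targets],
        truth=truth,
        seed=spec.seed,
        times=np.asarray(times, dtype=float),
    )


def make_nonidentifiable_fixture(
    spec: ChainModelSpec,
    times: np.ndarray | None = None,
    noise_cv: float = 0.0,
) -> StudyFixture:
    """Variant fitting ``Import_M1_k`` and ``fu_M1`` together.

    Both enter the dynamics only through their product, so the data
    constrain the product while each factor is free to wander — the
    constructed negative control for the identifiability analysis.
    """
    return make_study_fixture(spec, times, noise_cv,
                              fit_targets=["Import_M1_k", "fu_M1"])


def write_fixture(fixture: StudyFixture, outdir: str | os.PathLike) -> dict[str, str]:
    """Write model.xml, data.csv, ranges.txt and truth.csv; returns paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, name) for name in
             ("model.xml", "data.csv", "ranges.txt", "truth.csv")}
    with open(paths["model.xml"], "w", encoding="utf-8") as fh:
        fh.write(write_sbml(fixture.model))

    # data.csv via the trajectory writer format (time + species columns)
    from .solvers import Trajectory
    cols = list(fixture.data.columns)
    values = np.column_stack([fixture.data.columns[c] for c in cols])
    traj = Trajectory(times=fixture.data.times, values=values, column_ids=cols)
    write_trajectory_csv(traj, paths["data.csv"])

    with open(paths["ranges.txt"], "w", encoding="utf-8") as fh:
        fh.write("# id initMin initMax min max\n")
        for s in fixture.parameters:
            fh.write(f"{s.id} {s.init_min!r} {s.init_max!r} "
                     f"{s.min!r} {s.max!r}\n")
    with open(paths["truth.csv"], "w", encoding="utf-8") as fh:
        fh.write("parameter,value\n")
        for pid, val in fixture.truth.items():
            fh.write(f"{pid},{val!r}\n")
    return paths
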