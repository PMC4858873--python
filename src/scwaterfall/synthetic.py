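"""Ground-truthed simulator for a branching stem-cell lineage.

The generator emulates the structure of a FACS-sorted head stem-cell
cohort: a main stem-cell trunk (an early proliferative state giving rise to
a pluripotent-like state) that bifurcates into a neural-primed lineage and a
separate differentiation lineage that crosses the X1 -> X2 FACS-gate
boundary.  Each cell has a true pseudotime t in [0, 1] and a branch; gene
means follow smooth per-branch profiles (flat, logistic up/down, or a
Gaussian peak at a state transition), scaled by a log-normal per-cell
library size.  Counts are negative binomial with per-gene overdispersion,
thinned by a dropout probability that is a logistic function of the log
expected mean — the minimal noise model consistent with single-cell
overdispersion and dropout.

Designated marker blocks mirror the biology the analysis must recover:
stem-cell markers fall along both branches, neural markers rise on the
neural branch only, cell-cycle markers fall late, one block peaks at the
neural transition, another at the gate crossing of the differentiation
branch, and a share of background genes switches off along the
differentiation branch so that the number of detected transcripts per cell
declines as cells leave the stem compartment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .counts_io import CountsMatrix

PROFILE_KINDS = ("flat", "logistic_inc", "logistic_dec", "gaussian_peak")


@dataclass(frozen=True)
class GeneProfile:
    """Smooth mean-expression profile over pseudotime for one branch."""

    kind: str
    baseline: float = 0.0
    amplitude: float = 0.0
    midpoint: float = 0.5   # logistic midpoint or peak time
    scale: float = 0.1      # logistic steepness or Gaussian width

    def __post_init__(self) -> None:
        if self.kind not in PROFILE_KINDS:
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.baseline < 0 or self.amplitude < 0:
            raise ValueError("profile means must be non-negative")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "flat":
            return np.full_like(t, self.baseline)
        if self.kind == "logistic_inc":
            return self.baseline + self.amplitude * expit(
                (t - self.midpoint) / self.scale
            )
        if self.kind == "logistic_dec":
            return self.baseline + self.amplitude * expit(
                -(t - self.midpoint) / self.scale
            )
        return self.baseline + self.amplitude * np.exp(
            -((t - self.midpoint) ** 2) / (2 * self.scale**2)
        )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "baseline": self.baseline,
            "amplitude": self.amplitude,
            "midpoint": self.midpoint,
            "scale": self.scale,
        }


@dataclass
class LineageModel:
    """Generative description of a branching lineage.

    ``profiles`` maps gene id -> branch name -> :class:`GeneProfile`.
    ``group_rule`` assigns true state labels from (branch, t): a sorted list
    of (upper time bound, label) per branch.  ``gate_rule`` maps a branch to
    the pseudotime threshold beyond which cells fall in the X2 FACS gate
    (None = branch stays X1).
    """

    branch_names: list[str]
    branch_point: float
    branch_weights: list[float]
    profiles: dict[str, dict[str, GeneProfile]]
    dispersion: dict[str, float]
    dropout_intercept: float
    dropout_slope: float
    library_sigma: float
    gate_rule: dict[str, float | None]
    group_rule: dict[str, list[tuple[float, str]]]
    marker_panels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.branch_weights), 1.0):
            raise ValueError("branch weights must sum to 1")
        if self.library_sigma < 0:
            raise ValueError("library sigma must be >= 0")
        for g, per_branch in self.profiles.items():
            for b in self.branch_names:
                if b not in per_branch:
                    raise ValueError(f"gene {g} lacks a profile for branch {b}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.profiles)

    def mean_expression(self, gene: str, branch: str, t) -> np.ndarray:
        """Expected expression of ``gene`` at pseudotime ``t`` on ``branch``
        (library size 1, before dropout)."""
        return self.profiles[gene][branch](t)

    def dropout_probability(self, mu) -> np.ndarray:
        return expit(
            self.dropout_intercept + self.dropout_slope * np.log(np.asarray(mu) + 1.0)
        )

    def group_of(self, branch: str, t: float) -> str:
        for upper, label in self.group_rule[branch]:
            if t < upper:
                return label
        return self.group_rule[branch][-1][1]

    def gate_of(self, branch: str, t: float) -> str:
        thr = self.gate_rule.get(branch)
        return "X2" if thr is not None and t >= thr else "X1"

    # -- config round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "branch_names": self.branch_names,
            "branch_point": self.branch_point,
            "branch_weights": list(self.branch_weights),
            "profiles": {
                g: {b: p.to_dict() for b, p in per.items()}
                for g, per in self.profiles.items()
            },
            "dispersion": dict(self.dispersion),
            "dropout_intercept": self.dropout_intercept,
            "dropout_slope": self.dropout_slope,
            "library_sigma": self.library_sigma,
            "gate_rule": dict(self.gate_rule),
            "group_rule": {
                b: [[u, lab] for u, lab in rules]
                for b, rules in self.group_rule.items()
            },
            "marker_panels": {k: list(v) for k, v in self.marker_panels.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LineageModel":
        return cls(
            branch_names=list(d["branch_names"]),
            branch_point=float(d["branch_point"]),
            branch_weights=list(d["branch_weights"]),
            profiles={
                g: {b: GeneProfile(**p) for b, p in per.items()}
                for g, per in d["profiles"].items()
            },
            dispersion={k: float(v) for k, v in d["dispersion"].items()},
            dropout_intercept=float(d["dropout_intercept"]),
            dropout_slope=float(d["dropout_slope"]),
            library_sigma=float(d["library_sigma"]),
            gate_rule={
                k: (None if v is None else float(v))
                for k, v in d["gate_rule"].items()
            },
            group_rule={
                b: [(float(u), str(lab)) for u, lab in rules]
                for b, rules in d["group_rule"].items()
            },
            marker_panels={
                k: list(v) for k, v in d.get("marker_panels", {}).items()
            },
        )

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))
        return path

    @classmethod
    def load(cls, path) -> "LineageModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated cohort.

    ``table`` is indexed by cell id with columns branch, t_true,
    group_true, gate.
    """

    table: pd.DataFrame
    seed: int
    model: LineageModel

    def export(self, path) -> Path:
        path = Path(path)
        self.table.to_csv(path, sep="\t", float_format="%.10g")
        return path


# ---------------------------------------------------------------------------
# default model


def default_planarian_model(n_genes: int = 1200) -> LineageModel:
    """Default branching model emulating the head stem-cell cohort.

    Trunk: early proliferative state (Group2, t < 0.25) -> pluripotent-like
    state (Group1).  At t = 0.5 the lineage bifurcates into the neural
    branch ("nu": Group1 -> nuNeoblast) and the differentiation branch
    ("x2": Group1 -> Group4 -> Group5 -> Group6), which crosses into the X2
    FACS gate at t = 0.75.  Branch-specific programs ramp up with steep
    logistics centered after the branch point, so pre-branch divergence is
    small (mild transcriptional priming).
    """
    if n_genes < 50:
        raise ValueError("need at least 50 genes")
    profiles: dict[str, dict[str, GeneProfile]] = {}
    dispersion: dict[str, float] = {}
    panels: dict[str, list[str]] = {
        "stem": [], "neural": [], "cycle": [],
        "transition_peak": [], "branchB_peak": [], "housekeeping": [],
    }

    def add(gene, nu_prof, x2_prof, disp=0.3):
        profiles[gene] = {"nu": nu_prof, "x2": x2_prof}
        dispersion[gene] = disp

    # marker parameters are drawn from a fixed internal stream: real marker
    # cohorts turn over at staggered times and rates, which is also what
    # makes position along the trajectory identifiable everywhere
    prng = np.random.default_rng(777000)

    flat_low = GeneProfile("flat", baseline=0.5)
    for i in range(30):
        g = f"stem-{i + 1:02d}"
        p = GeneProfile(
            "logistic_dec", baseline=1.0,
            amplitude=float(np.exp(prng.uniform(np.log(20), np.log(80)))),
            midpoint=float(prng.uniform(0.2, 0.7)),
            scale=float(prng.uniform(0.08, 0.2)),
        )
        add(g, p, p)
        panels["stem"].append(g)
    for i in range(20):
        g = f"neural-{i + 1:02d}"
        p = GeneProfile(
            "logistic_inc", baseline=0.5,
            amplitude=float(np.exp(prng.uniform(np.log(20), np.log(80)))),
            midpoint=float(prng.uniform(0.55, 0.8)),
            scale=float(prng.uniform(0.05, 0.1)),
        )
        add(g, p, flat_low)
        panels["neural"].append(g)
    for i in range(20):
        g = f"cycle-{i + 1:02d}"
        p = GeneProfile(
            "logistic_dec", baseline=1.0,
            amplitude=float(np.exp(prng.uniform(np.log(20), np.log(60)))),
            midpoint=float(prng.uniform(0.5, 0.75)),
            scale=float(prng.uniform(0.06, 0.12)),
        )
        add(g, p, p)
        panels["cycle"].append(g)
    for i in range(10):
        g = f"transition-peak-{i + 1:02d}"
        p = GeneProfile("gaussian_peak", baseline=0.5, amplitude=45.0,
                        midpoint=0.55, scale=0.08)
        add(g, p, flat_low)
        panels["transition_peak"].append(g)
    for i in range(10):
        g = f"branchB-peak-{i + 1:02d}"
        p = GeneProfile("gaussian_peak", baseline=0.5, amplitude=45.0,
                        midpoint=0.75, scale=0.08)
        add(g, flat_low, p)
        panels["branchB_peak"].append(g)

    # fixed internal stream so the model itself is deterministic
    rng = np.random.default_rng(777001)

    # ubiquitous housekeeping transcripts (tubulin-like): high expression,
    # low dispersion, detected in essentially every cell — these anchor the
    # median-of-ratios reference set
    hk_levels = np.exp(rng.uniform(np.log(100.0), np.log(400.0), size=20))
    for i in range(20):
        g = f"housekeeping-{i + 1:02d}"
        p = GeneProfile("flat", baseline=float(hk_levels[i]))
        add(g, p, p, disp=0.15)
        panels["housekeeping"].append(g)

    # background
    n_bg = n_genes - len(profiles)
    baselines = np.exp(rng.uniform(np.log(0.5), np.log(40.0), size=n_bg))
    declining = rng.random(n_bg) < 0.4
    for i in range(n_bg):
        g = f"bg-{i + 1:04d}"
        b = float(baselines[i])
        if declining[i]:
            # switches off along the differentiation branch only: fewer
            # transcripts detected late on that branch
            nu_p = GeneProfile("flat", baseline=b)
            x2_p = GeneProfile("logistic_dec", baseline=0.05 * b,
                               amplitude=0.95 * b, midpoint=0.7, scale=0.08)
        else:
            nu_p = x2_p = GeneProfile("flat", baseline=b)
        add(g, nu_p, x2_p, disp=0.4)

    return LineageModel(
        branch_names=["nu", "x2"],
        branch_point=0.5,
        branch_weights=[0.5, 0.5],
        profiles=profiles,
        dispersion=dispersion,
        dropout_intercept=1.0,
        dropout_slope=-1.5,
        library_sigma=0.3,
        gate_rule={"nu": None, "x2": 0.75},
        group_rule={
            "nu": [(0.25, "Group2"), (0.55, "Group1"), (1.01, "nuNeoblast")],
            "x2": [(0.25, "Group2"), (0.5, "Group1"), (0.67, "Group4"),
                   (0.84, "Group5"), (1.01, "Group6")],
        },
        marker_panels=panels,
    )


# ---------------------------------------------------------------------------
# simulation


def simulate(
    model: LineageModel,
    n_cells: int,
    seed: int,
    fixed_t: float | None = None,
    fixed_branch: str | None = None,
) -> tuple[CountsMatrix, SyntheticTruth]:
    """Draw a cohort of cells from the model, fully reproducible from seed.

    Per cell: branch ~ categorical(branch_weights), t ~ Uniform(0, 1),
    library size ~ LogNormal(0, library_sigma).  Per gene: mean =
    library x profile(t); counts ~ NegativeBinomial(mean, per-gene
    dispersion) via the gamma-Poisson mixture, then zeroed with the dropout
    probability of the (pre-library-noise) log mean.  ``fixed_t`` /
    ``fixed_branch`` pin those draws for calibration checks.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    rng = np.random.default_rng(seed)
    if fixed_branch is not None:
        branches = np.array([fixed_branch] * n_cells)
    else:
        branches = rng.choice(
            model.branch_names, size=n_cells, p=model.branch_weights
        )
    if fixed_t is not None:
        t = np.full(n_cells, float(fixed_t))
    else:
        t = rng.uniform(0.0, 1.0, size=n_cells)
    if model.library_sigma > 0:
        lib = rng.lognormal(0.0, model.library_sigma, size=n_cells)
    else:
        lib = np.ones(n_cells)

    genes = model.gene_ids
    counts = np.zeros((len(genes), n_cells), dtype=np.int64)
    branch_masks = {b: branches == b for b in model.branch_names}
    for gi, g in enumerate(genes):
        mu_profile = np.empty(n_cells)
        for b, mask in branch_masks.items():
            if mask.any():
                mu_profile[mask] = model.mean_expression(g, b, t[mask])
        mu = mu_profile * lib
        alpha = model.dispersion[g]
        if alpha <= 1e-12:
            draws = rng.poisson(mu)
        else:
            lam = rng.gamma(1.0 / alpha, alpha * mu)
            draws = rng.poisson(lam)
        p_drop = model.dropout_probability(mu_profile)
        dropped = rng.random(n_cells) < p_drop
        counts[gi] = np.where(dropped, 0, draws)

    cell_ids = [f"cell-{i + 1:04d}" for i in range(n_cells)]
    gates = [model.gate_of(b, ti) for b, ti in zip(branches, t)]
    meta = pd.DataFrame(
        {"gate": gates, "region": "head", "source": "synthetic"},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    m = CountsMatrix(
        gene_ids=list(genes), cell_ids=cell_ids, counts=counts, cell_meta=meta
    )
    truth = pd.DataFrame(
        {
            "branch": branches,
            "t_true": t,
            "group_true": [
                model.group_of(b, ti) for b, ti in zip(branches, t)
            ],
            "gate": gates,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return m, SyntheticTruth(table=truth, seed=seed, model=model)


def truth_alignment(pt, truth: SyntheticTruth) -> dict:
    """Compare inferred pseudotime against ground truth.

    ``pt`` is a PseudotimeResult (or any object with ``cell_ids`` and
    ``pseudotime``).  Returns Spearman correlation and orientation sign per
    branch (branches with < 3 evaluated cells are skipped) plus an "all"
    entry over every matched cell; ``overall`` is |rho| over all cells.
    """
    inferred = pd.Series(pt.pseudotime, index=pt.cell_ids)
    tab = truth.table.loc[inferred.index]
    out: dict = {"branches": {}, "skipped": []}

    def _entry(x, y):
        rho = float(stats.spearmanr(x, y).statistic)
        return {"spearman": rho, "sign": int(np.sign(rho)) if rho == rho else 0,
                "n": int(len(x))}

    for b in truth.model.branch_names:
        mask = tab["branch"] == b
        if mask.sum() < 3:
            out["skipped"].append(b)
            continue
        out["branches"][b] = _entry(
            inferred[mask].to_numpy(), tab.loc[mask, "t_true"].to_numpy()
        )
    out["all"] = _entry(inferred.to_numpy(), tab["t_true"].to_numpy())
    out["overall"] = abs(out["all"]["spearman"])
    return out
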