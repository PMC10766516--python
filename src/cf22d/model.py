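"""Supervised training of the energy functional.

The model couples a reaction database to the linear descriptor
representation of the density-functional energy and an optional
geometry-based dispersion term.  For a reaction with stoichiometric
coefficients nu_s the predicted value is

    sum_s nu_s (E_DF,s(theta) + E_disp,s(s_r6))     (converted to kcal/mol),

exactly linear in the 59 density-functional parameters theta = (X, a, b, c)
for fixed s_r6.  Training minimises

    L = sum_n R_n / I_n + lambda (a + b + c)

over the training-role data sets (R_n the per-set RMSE in kcal/mol, I_n the
inverse weight) with the smoothness penalty built from adjacent-coefficient
differences.  The range parameter s_r6 is selected by a coarse scan with
interval refinement against the pooled training MUE, and validation sets
whose MUE exceeds the reference panel statistic by more than the trigger
fraction are promoted into the training set, iterating to convergence.

Usage follows the model/results convention::

    problem = TrainingProblem(database, dispersion_params, config)
    results = problem.fit()
    print(results.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .units import KCALMOL_PER_HARTREE
from .database import Database, DataSet, ReactionRecord
from .dispersion.energy import DispersionParams, dispersion_energy, DEFAULT_SR6
from .xc.indices import enumerate_a_indices, N_A_TERMS, N_B_TERMS, N_C_TERMS, N_DF_PARAMS
from .xc.params import XCParameters
from .stats import mue as _mue, rmse as _rmse

__all__ = [
    "TrainingConfig", "TrainingProblem", "TrainingResults", "TrainState",
    "Promotion", "regularization_terms", "TrainingLoopError",
]

_logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# regularization
# ---------------------------------------------------------------------------

def regularization_terms(params: XCParameters) -> tuple[float, float, float]:
    """Adjacent-difference smoothness sums (a, b, c).

    The a-sum couples coefficients adjacent in k within each (i, j) family
    (k up to 4 - i - j); the b- and c-sums are plain adjacent differences.
    """
    order = enumerate_a_indices()
    pos = {ijk: n for n, ijk in enumerate(order)}
    a_sum = 0.0
    for i in range(4):
        for j in range(4 - i):
            for k in range(5 - i - j):
                d = params.a[pos[(i, j, k)]] - params.a[pos[(i, j, k + 1)]]
                a_sum += d * d
    b_sum = float(np.sum(np.diff(params.b) ** 2))
    c_sum = float(np.sum(np.diff(params.c) ** 2))
    return a_sum, b_sum, c_sum


def _difference_operator() -> np.ndarray:
    """Matrix D with ||D theta||^2 = a + b + c on the 59-vector theta."""
    order = enumerate_a_indices()
    pos = {ijk: n for n, ijk in enumerate(order)}
    rows = []
    for i in range(4):
        for j in range(4 - i):
            for k in range(5 - i - j):
                row = np.zeros(N_DF_PARAMS)
                row[1 + pos[(i, j, k)]] = 1.0
                row[1 + pos[(i, j, k + 1)]] = -1.0
                rows.append(row)
    for blk, off in (("b", 1 + N_A_TERMS), ("c", 1 + N_A_TERMS + N_B_TERMS)):
        for i in range(8):
            row = np.zeros(N_DF_PARAMS)
            row[off + i] = 1.0
            row[off + i + 1] = -1.0
            rows.append(row)
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# configuration and state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingConfig:
    """Knobs of the loss and of the supervised loop.

    lambda_ is the smoothing coefficient of the loss (0.01 for the trained
    functional); sr6 bounds/step define the range-parameter scan (angstrom
    scale); trigger is the promotion fraction (0.30); mue_tol the
    convergence tolerance on the pooled training MUE between iterations
    (kcal/mol).
    """

    lambda_: float = 0.01
    sr6_min: float = 1.2
    sr6_max: float = 2.1
    sr6_step: float = 0.1
    sr6_tol: float = 0.004
    trigger: float = 0.30
    mue_tol: float = 1e-3
    max_iter: int = 50
    n_starts: int = 2
    maxiter_opt: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be non-negative")
        if self.trigger <= 0:
            raise ValueError("trigger fraction must be positive")
        if not (self.sr6_min < self.sr6_max):
            raise ValueError("sr6 bounds must be ordered")


@dataclass(frozen=True)
class Promotion:
    iteration: int
    set_id: str
    mue: float
    panel: float
    threshold: float


@dataclass(frozen=True)
class TrainState:
    """Snapshot of the supervised loop."""

    params: XCParameters
    sr6: float
    database: Database
    iteration: int
    per_set_mue: dict
    promotion_log: tuple[Promotion, ...]
    training_mue: float
    refresh_tag: int = 0


class TrainingLoopError(RuntimeError):
    """Raised when the loop hits its iteration cap; carries the last state."""

    def __init__(self, message: str, state: TrainState):
        super().__init__(message)
        self.state = state


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class TrainingProblem:
    """Couples a database to the linear energy model; ``fit()`` trains it.

    Parameters
    ----------
    database : Database
        Species (descriptors + optional geometries) and data sets.
    dispersion : DispersionParams or None
        Template dispersion parameters; its sr6 is overridden during the
        scan.  None disables the dispersion term (and the sr6 scan).
    config : TrainingConfig
    """

    def __init__(self, database: Database, dispersion: DispersionParams | None = None,
                 config: TrainingConfig | None = None):
        self.database = database
        self.dispersion = dispersion
        self.config = config or TrainingConfig()
        self._D = _difference_operator()
        self._R = self._D.T @ self._D
        self._species_rows = {
            sid: sp.descriptors.stacked() for sid, sp in database.species.items()
        }
        self._disp_cache: dict[tuple[str, float], float] = {}
        # per-dataset design matrices (kcal/mol scale), built lazily
        self._design_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._offset_cache: dict[tuple[str, float], np.ndarray] = {}

    @classmethod
    def from_manifest(cls, path, dispersion: DispersionParams | None = None,
                      config: TrainingConfig | None = None) -> "TrainingProblem":
        from .database import read_manifest

        return cls(read_manifest(path), dispersion, config)

    # -- per-species pieces -------------------------------------------------

    def species_dispersion(self, species_id: str, sr6: float) -> float:
        """Dispersion energy of one species (hartree), cached per sr6."""
        if self.dispersion is None:
            return 0.0
        key = (species_id, round(float(sr6), 12))
        if key not in self._disp_cache:
            geom = self.database.species[species_id].geometry
            self._disp_cache[key] = (
                0.0 if geom is None
                else dispersion_energy(geom, self.dispersion.with_sr6(sr6))
            )
        return self._disp_cache[key]

    def predicted_value(self, record: ReactionRecord, params: XCParameters, sr6: float) -> float:
        """Stoichiometric sum of species energies, in kcal/mol."""
        theta = params.to_vector()
        total = 0.0
        for sid, nu in record.species.items():
            if sid not in self._species_rows:
                raise KeyError(f"record references unknown species {sid!r}")
            e_df = float(self._species_rows[sid] @ theta)
            total += nu * (e_df + self.species_dispersion(sid, sr6))
        return total * KCALMOL_PER_HARTREE

    # -- vectorised design --------------------------------------------------

    def _dataset_design(self, ds: DataSet) -> tuple[np.ndarray, np.ndarray]:
        """(A, y): A theta (kcal/mol) is the dispersion-free prediction."""
        if ds.id not in self._design_cache:
            A = np.zeros((ds.size, N_DF_PARAMS))
            y = np.empty(ds.size)
            for r, rec in enumerate(ds.records):
                for sid, nu in rec.species.items():
                    A[r] += nu * self._species_rows[sid]
                y[r] = rec.reference_kcal
            self._design_cache[ds.id] = (A * KCALMOL_PER_HARTREE, y)
        return self._design_cache[ds.id]

    def _dataset_offsets(self, ds: DataSet, sr6: float) -> np.ndarray:
        """Per-record dispersion offsets (kcal/mol)."""
        key = (ds.id, round(float(sr6), 12))
        if key not in self._offset_cache:
            off = np.array(
                [
                    sum(nu * self.species_dispersion(sid, sr6) for sid, nu in rec.species.items())
                    for rec in ds.records
                ]
            )
            self._offset_cache[key] = off * KCALMOL_PER_HARTREE
        return self._offset_cache[key]

    def residuals(self, ds: DataSet, params: XCParameters, sr6: float) -> np.ndarray:
        """Prediction minus reference, kcal/mol."""
        A, y = self._dataset_design(ds)
        return A @ params.to_vector() + self._dataset_offsets(ds, sr6) - y

    def set_mue(self, ds: DataSet, params: XCParameters, sr6: float) -> float:
        return _mue(self.residuals(ds, params, sr6))

    def training_mue(self, params: XCParameters, sr6: float,
                     database: Database | None = None) -> float:
        """Pooled MUE over every training-role record (kcal/mol)."""
        db = database or self.database
        res = [self.residuals(ds, params, sr6) for ds in db.by_role("training")]
        if not res:
            raise ValueError("database has no training-role data sets")
        return _mue(np.concatenate(res))

    # -- loss and fitting ---------------------------------------------------

    def loss(self, params: XCParameters, sr6: float,
             database: Database | None = None) -> float:
        """L = sum_n R_n / I_n + lambda (a + b + c) over training sets."""
        db = database or self.database
        training = db.by_role("training")
        if not training:
            raise ValueError("database has no training-role data sets")
        data_term = sum(
            _rmse(self.residuals(ds, params, sr6)) / ds.inverse_weight for ds in training
        )
        a, b, c = regularization_terms(params)
        return data_term + self.config.lambda_ * (a + b + c)

    def _loss_and_grad(self, theta: np.ndarray, blocks, lam: float) -> tuple[float, np.ndarray]:
        eps = 1e-30
        f = lam * float(theta @ self._R @ theta)
        g = 2.0 * lam * (self._R @ theta)
        for A, t, inv_w in blocks:
            r = A @ theta - t
            m = float(np.mean(r * r))
            s = np.sqrt(m + eps)
            f += s / inv_w
            g += (A.T @ r) / (inv_w * s * r.size)
        return f, g

    def fit_parameters(self, sr6: float, theta_init: XCParameters | None = None,
                       database: Database | None = None) -> XCParameters:
        """Minimise the loss at fixed sr6.

        Deterministic given the config seed: a closed-form weighted ridge
        solve seeds a multi-start quasi-Newton polish of the exact loss; the
        returned parameters never have higher loss than ``theta_init``.
        """
        db = database or self.database
        training = db.by_role("training")
        if not training:
            raise ValueError("database has no training-role data sets")
        lam = self.config.lambda_
        blocks = []
        for ds in training:
            A, y = self._dataset_design(ds)
            blocks.append((A, y - self._dataset_offsets(ds, sr6), ds.inverse_weight))

        # closed-form surrogate: sum_n MSE_n/I_n + lambda ||D theta||^2
        rows = [A / np.sqrt(inv_w * A.shape[0]) for A, _, inv_w in blocks]
        rhs = [t / np.sqrt(inv_w * t.size) for _, t, inv_w in blocks]
        if lam > 0:
            rows.append(np.sqrt(lam) * self._D)
            rhs.append(np.zeros(self._D.shape[0]))
        M = np.vstack(rows)
        v = np.concatenate(rhs)
        scale = np.linalg.norm(M, axis=0)
        scale[scale == 0] = 1.0
        theta_ls, *_ = np.linalg.lstsq(M / scale, v, rcond=None)
        theta_ls = theta_ls / scale

        rng = np.random.default_rng(self.config.seed)
        starts = [theta_ls]
        if theta_init is not None:
            starts.append(theta_init.to_vector())
        span = max(1.0, float(np.max(np.abs(theta_ls))))
        for _ in range(max(0, self.config.n_starts - 1)):
            starts.append(theta_ls + rng.normal(scale=0.05 * span, size=N_DF_PARAMS))

        def true_loss(theta: np.ndarray) -> float:
            return self.loss(XCParameters.from_vector(theta), sr6, db)

        best = min(starts, key=true_loss)
        for x0 in starts:
            res = minimize(
                self._loss_and_grad, x0, args=(blocks, lam), jac=True,
                method="L-BFGS-B",
                options={"maxiter": self.config.maxiter_opt, "ftol": 1e-14, "gtol": 1e-12},
            )
            if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
                bad = training[0].id
                raise FloatingPointError(
                    f"non-finite loss during optimisation (first training set {bad!r})"
                )
            if true_loss(res.x) < true_loss(best):
                best = res.x
        if theta_init is not None and true_loss(theta_init.to_vector()) <= true_loss(best):
            return theta_init
        return XCParameters.from_vector(best)

    # -- sr6 scan -----------------------------------------------------------

    def scan_sr6(self, theta_init: XCParameters | None = None,
                 database: Database | None = None) -> tuple[float, XCParameters]:
        """Coarse grid then interval refinement on the training MUE.

        The selection criterion is the pooled training-set MUE (not the
        loss); exact ties break toward smaller sr6, and the result never
        leaves the configured bounds.
        """
        cfg = self.config
        db = database or self.database

        def evaluate(sr6: float) -> tuple[float, XCParameters]:
            theta = self.fit_parameters(sr6, theta_init, db)
            return self.training_mue(theta, sr6, db), theta

        cache: dict[float, tuple[float, XCParameters]] = {}

        def ev(sr6: float) -> tuple[float, XCParameters]:
            key = round(sr6, 10)
            if key not in cache:
                cache[key] = evaluate(key)
            return cache[key]

        grid = np.arange(cfg.sr6_min, cfg.sr6_max + 1e-9, cfg.sr6_step)
        best_sr6 = None
        best_mue = np.inf
        for s in grid:  # ascending: ties keep the smaller sr6
            m, _ = ev(float(s))
            if m < best_mue - 1e-12:
                best_mue, best_sr6 = m, float(s)
        step = cfg.sr6_step / 2.0
        while step > cfg.sr6_tol:
            for cand in (best_sr6 - step, best_sr6 + step):
                if cand < cfg.sr6_min - 1e-9 or cand > cfg.sr6_max + 1e-9:
                    continue
                cand = min(max(cand, cfg.sr6_min), cfg.sr6_max)
                m, _ = ev(cand)
                if m < best_mue - 1e-12:
                    best_mue, best_sr6 = m, cand
                elif abs(m - best_mue) <= 1e-12 and cand < best_sr6:
                    best_sr6 = cand
            step /= 2.0
        return best_sr6, ev(best_sr6)[1]

    # -- supervised promotion -----------------------------------------------

    def supervised_update(self, params: XCParameters, sr6: float,
                          database: Database | None = None,
                          iteration: int = 0) -> tuple[list[Promotion], Database]:
        """Promote validation sets whose MUE exceeds the panel threshold.

        A set is promoted iff MUE > (1 + trigger) * panel, strictly; the
        promoted set keeps the panel statistic as its new inverse weight.
        Returns the (possibly empty) promotion list and the updated
        database; set order follows the manifest.
        """
        db = database or self.database
        promotions: list[Promotion] = []
        for ds in db.by_role("validation"):
            if ds.reference_mue_mean is None:
                raise ValueError(
                    f"validation set {ds.id!r} lacks its reference panel statistic"
                )
            m = self.set_mue(ds, params, sr6)
            threshold = (1.0 + self.config.trigger) * ds.reference_mue_mean
            if m > threshold:
                promotions.append(Promotion(iteration, ds.id, m, ds.reference_mue_mean, threshold))
                _logger.info(
                    "event=promotion iteration=%d set=%s mue=%.6f panel=%.6f threshold=%.6f",
                    iteration, ds.id, m, ds.reference_mue_mean, threshold,
                )
        for p in promotions:
            db = db.with_role(p.set_id, "training", inverse_weight=p.panel)
        return promotions, db

    # -- the loop -----------------------------------------------------------

    def fit(self, sr6: float | None = None, theta_init: XCParameters | None = None,
            refresh_hook=None) -> "TrainingResults":
        """Run the full supervised loop and return a results object.

        Iterates fit -> evaluate -> promote (-> density refresh hook) until
        no promotion occurs and the pooled training MUE has stabilised.
        ``sr6`` fixes the range parameter and disables the scan; otherwise
        the scan runs when a dispersion term is present (without one the
        scan objective is flat and the tie rule returns the lower bound).
        """
        cfg = self.config
        db = self.database
        log: list[Promotion] = []
        prev_mue = np.inf
        params = theta_init
        cur_sr6 = sr6 if sr6 is not None else DEFAULT_SR6
        refresh_tag = 0
        iteration = 0
        while True:
            iteration += 1
            if iteration > cfg.max_iter:
                state = TrainState(params, cur_sr6, db, iteration - 1, {}, tuple(log),
                                   prev_mue, refresh_tag)
                raise TrainingLoopError(
                    f"training loop exceeded {cfg.max_iter} iterations", state
                )
            if sr6 is None and self.dispersion is not None:
                cur_sr6, params = self.scan_sr6(theta_init, db)
            else:
                params = self.fit_parameters(cur_sr6, theta_init, db)
            train_mue = self.training_mue(params, cur_sr6, db)
            per_set = {ds.id: self.set_mue(ds, params, cur_sr6) for ds in db.datasets}
            promotions, db = self.supervised_update(params, cur_sr6, db, iteration)
            log.extend(promotions)
            # without a density-refresh hook the fit is a deterministic fixed
            # point, so "no promotion" already implies convergence
            mue_open = refresh_hook is not None and abs(prev_mue - train_mue) >= cfg.mue_tol
            if promotions or mue_open:
                if refresh_hook is not None:
                    refresh_hook(iteration, db)
                    refresh_tag += 1
                prev_mue = train_mue
                continue
            state = TrainState(params, cur_sr6, db, iteration, per_set, tuple(log),
                               train_mue, refresh_tag)
            return TrainingResults(self, state)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

class TrainingResults:
    """Fitted parameters, diagnostics and a summary table."""

    def __init__(self, problem: TrainingProblem, state: TrainState):
        self.problem = problem
        self.state = state
        self.params: XCParameters = state.params
        self.sr6: float = state.sr6
        self.database: Database = state.database
        self.training_mue: float = state.training_mue
        self.promotion_log = state.promotion_log
        self.n_iterations = state.iteration
        self.loss = problem.loss(self.params, self.sr6, self.database)

    def per_set_table(self) -> pd.DataFrame:
        rows = []
        for ds in self.database.datasets:
            res = self.problem.residuals(ds, self.params, self.sr6)
            rows.append(
                {
                    "set_id": ds.id, "role": ds.role, "class": ds.property_class,
                    "n": ds.size, "inverse_weight": ds.inverse_weight,
                    "mue": _mue(res), "rmse": _rmse(res),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        a, b, c = regularization_terms(self.params)
        lines = [
            "Energy-functional training results",
            "=" * 50,
            f"iterations            {self.n_iterations}",
            f"promotions            {len(self.promotion_log)}",
            f"s_r6                  {self.sr6:.4f}",
            f"X (% HF exchange)     {self.params.x:.6f}",
            f"training MUE          {self.training_mue:.6f} kcal/mol",
            f"loss                  {self.loss:.6f}",
            f"smoothness (a, b, c)  ({a:.4g}, {b:.4g}, {c:.4g})",
            "",
            self.per_set_table().to_string(index=False),
        ]
        if self.promotion_log:
            lines.append("")
            lines.append("promotions (iteration, set, MUE, panel, threshold):")
            for p in self.promotion_log:
                lines.append(
                    f"  {p.iteration:3d}  {p.set_id:<20s} {p.mue:9.4f} {p.panel:9.4f} {p.threshold:9.4f}"
                )
        return "\n".join(lines)
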