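"""Assemble simulation designs into simulated longitudinal datasets.

The model: a single transformed-scale feature is drawn from a (truncated)
multivariate normal ``Y ~ N(mu, Sigma)`` over ``n = n_control + n_treat``
subjects with ``q_i`` repeated measurements each. Control subjects have
constant mean ``mu_0``; treatment subjects have mean ``mu_0 + f(t)`` where
``f`` is a :class:`~ldasim.trends.TrendSpec`. Within-subject correlation is
AR(1), compound-symmetric or independent; subjects are independent, so
``Sigma`` is block diagonal. Missingness is induced after sampling by
overwriting randomly chosen non-baseline cells of ``Y_obs`` with an imputed
value (0) or a not-available marker, while ``Y`` keeps the complete data.

Multi-feature "community" simulation repeats the single-feature draw with
independent noise per feature on a shared sampling schedule, yielding the
familiar feature-by-sample abundance table plus sample metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .covariance import BlockCovariance, CovarianceSpec, block_covariance
from .sampling import TruncationSpec, sample_truncated_mvn
from .trends import TrendSpec, TrendValidationError, evaluate_trend, validate_trend

__all__ = [
    "NA",
    "SimulationDesign",
    "SimulatedDataset",
    "CommunityDataset",
    "make_timepoints",
    "build_mean_vector",
    "simulate_feature",
    "induce_missingness",
    "simulate_community",
    "simulate_from_design",
]

#: distinguished not-available marker for miss_val (serialized as "NA")
NA = float("nan")

CONTROL, TREATMENT = "Control", "Treatment"


@dataclass(frozen=True)
class SimulationDesign:
    """Full parameterization of one simulated feature.

    Parameters
    ----------
    n_control, n_treat
        Subjects per arm; control subjects get IDs 1..n_control, treatment
        the remainder.
    control_mean
        Baseline mean ``mu_0`` shared by both arms (abundance units).
    covariance
        Within-subject covariance structure (sigma, rho, structure).
    trend
        Differential-abundance function ``f(t)`` added to the treatment
        mean.
    num_timepoints
        Repeated measurements per subject, q >= 2.
    t_interval
        Study interval ``(t1, tq)``.
    asynch_time
        If True, each subject's non-baseline times are drawn uniformly on
        the interval (baseline is always observed at t1); otherwise all
        subjects share the q equidistant points.
    missing_pct
        Fraction of subjects to receive missing values, in [0, 1].
    missing_per_subject
        Non-baseline measurements set missing per selected subject.
    miss_val
        Value written into ``Y_obs`` at missing cells: a number (e.g. 0,
        a feature present but undetected) or :data:`NA` (a sample never
        collected).
    truncation
        Left-truncation settings (zero truncation enabled by default).
    seed
        Seed for the design's random stream.
    """

    n_control: int
    n_treat: int
    control_mean: float
    covariance: CovarianceSpec
    trend: TrendSpec = field(default_factory=lambda: TrendSpec("none"))
    num_timepoints: int = 5
    t_interval: tuple[float, float] = (0.0, 10.0)
    asynch_time: bool = False
    missing_pct: float = 0.0
    missing_per_subject: int = 0
    miss_val: float = 0.0
    truncation: TruncationSpec = field(default_factory=TruncationSpec)
    seed: int = 0

    @property
    def n_subjects(self) -> int:
        return self.n_control + self.n_treat

    @property
    def n_total(self) -> int:
        """N = q * n when every subject has q measurements."""
        return self.n_subjects * self.num_timepoints

    def validate(self) -> list[str]:
        v = []
        if self.n_control < 1 or self.n_treat < 1:
            v.append("both arms need at least one subject")
        if self.num_timepoints < 2:
            v.append(f"num_timepoints must be >= 2, got {self.num_timepoints}")
        t1, tq = self.t_interval
        if not t1 < tq:
            v.append(f"t_interval must satisfy t1 < tq, got {self.t_interval}")
        if not 0 <= self.missing_pct <= 1:
            v.append(f"missing_pct must be in [0, 1], got {self.missing_pct}")
        if self.missing_per_subject < 0:
            v.append("missing_per_subject must be >= 0")
        if self.missing_per_subject > self.num_timepoints - 1:
            v.append(
                f"missing_per_subject = {self.missing_per_subject} exceeds the "
                f"{self.num_timepoints - 1} non-baseline timepoints "
                "(baseline can never be missing)"
            )
        v += self.covariance.validate()
        v += validate_trend(self.trend, self.t_interval)
        v += self.truncation.validate()
        return v

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimulatedDataset:
    """One simulated feature in long format.

    ``records`` has columns Y (complete outcome), ID, time, group, Y_obs
    (outcome after missingness), sorted by ID then time. ``mu`` and
    ``sigma`` are the mean vector and block covariance that generated Y.
    ``miss_data`` lists the (miss_id, miss_time) cells made missing.
    """

    records: pd.DataFrame
    mu: NDArray[np.float64]
    sigma: BlockCovariance
    n_total: int
    miss_data: pd.DataFrame
    sampling_modes: list[str]
    design: SimulationDesign | None = None

    @property
    def y(self) -> NDArray[np.float64]:
        return self.records["Y"].to_numpy()

    @property
    def y_obs(self) -> NDArray[np.float64]:
        return self.records["Y_obs"].to_numpy()

    def subject_times(self) -> dict[int, NDArray[np.float64]]:
        return {
            int(sid): g["time"].to_numpy()
            for sid, g in self.records.groupby("ID", sort=True)
        }


@dataclass
class CommunityDataset:
    """Multi-feature abundance matrix plus per-sample metadata.

    ``abundance`` is features x samples (rows Diff_Bug1.. then
    NoDiffBug_1.., columns Sample_1..Sample_N ordered by ID then time);
    ``sample_meta`` has one row per sample with ID, time, group, Sample_ID.
    """

    abundance: pd.DataFrame
    sample_meta: pd.DataFrame


def _empty_miss_data() -> pd.DataFrame:
    return pd.DataFrame({"miss_id": pd.Series(dtype=int), "miss_time": pd.Series(dtype=float)})


def make_timepoints(
    design: SimulationDesign, rng: np.random.Generator | None = None
) -> list[NDArray[np.float64]]:
    """Per-subject measurement times.

    Equidistant mode: every subject shares the q evenly spaced points from
    t1 to tq inclusive. Asynchronous mode: each subject keeps a baseline
    measurement at t1 and draws the remaining q-1 times i.i.d. uniform on
    (t1, tq), sorted ascending.
    """
    q = design.num_timepoints
    t1, tq = map(float, design.t_interval)
    n = design.n_subjects
    if not design.asynch_time:
        shared = np.linspace(t1, tq, q)
        return [shared] * n
    if rng is None:
        rng = design.rng()
    out = []
    for _ in range(n):
        extra = np.sort(rng.uniform(t1, tq, size=q - 1))
        out.append(np.concatenate(([t1], extra)))
    return out


def build_mean_vector(
    design: SimulationDesign, times: list[NDArray[np.float64]]
) -> NDArray[np.float64]:
    """Stacked N-vector of means: mu_0 for control, mu_0 + f(t) for treatment.

    In asynchronous mode the trend is evaluated at each treatment subject's
    own times; the decay anchor of oscillating trends stays at the design's
    tq regardless of the subject's last observed time.
    """
    violations = validate_trend(design.trend, design.t_interval)
    if violations:
        raise TrendValidationError(violations)
    mu0 = float(design.control_mean)
    tq = float(design.t_interval[1])
    pieces = []
    for i, t in enumerate(times):
        if i < design.n_control:
            pieces.append(np.full(t.shape, mu0))
        else:
            pieces.append(mu0 + evaluate_trend(design.trend, t, t_end=tq, validate=False))
    return np.concatenate(pieces)


def induce_missingness(
    dataset: SimulatedDataset,
    design: SimulationDesign,
    rng: np.random.Generator,
) -> SimulatedDataset:
    """Overwrite randomly selected non-baseline cells of Y_obs in place.

    ``round(missing_pct * n)`` subjects are chosen without replacement
    across both arms; for each, ``missing_per_subject`` of that subject's
    non-baseline times are chosen without replacement and Y_obs there is
    set to ``miss_val``. Y is untouched; baseline (each subject's first
    time) is never eligible.
    """
    if design.missing_per_subject > design.num_timepoints - 1:
        raise ValueError(
            f"missing_per_subject = {design.missing_per_subject} exceeds "
            f"q - 1 = {design.num_timepoints - 1}"
        )
    n = design.n_subjects
    n_miss_subjects = int(round(design.missing_pct * n))
    if n_miss_subjects == 0 or design.missing_per_subject == 0:
        dataset.miss_data = _empty_miss_data()
        return dataset

    subject_ids = np.arange(1, n + 1)
    chosen = np.sort(rng.choice(subject_ids, size=n_miss_subjects, replace=False))
    rec = dataset.records
    miss_ids, miss_times = [], []
    for sid in chosen:
        idx = rec.index[rec["ID"] == sid]
        non_baseline = idx[1:]  # records are sorted by time within subject
        pick = rng.choice(non_baseline, size=design.missing_per_subject, replace=False)
        for row in np.sort(pick):
            miss_ids.append(int(sid))
            miss_times.append(float(rec.at[row, "time"]))
            rec.at[row, "Y_obs"] = design.miss_val
    dataset.miss_data = pd.DataFrame({"miss_id": miss_ids, "miss_time": miss_times})
    return dataset


def _simulate_with_times(
    design: SimulationDesign,
    times: list[NDArray[np.float64]],
    rng: np.random.Generator,
    induce_missing: bool = True,
) -> SimulatedDataset:
    mu = build_mean_vector(design, times)
    qs = [len(t) for t in times]
    sigma = block_covariance(design.covariance, qs)
    mu_blocks = np.split(mu, np.cumsum(qs)[:-1])
    y, modes = sample_truncated_mvn(mu_blocks, sigma.blocks, design.truncation, rng)

    ids = np.repeat(np.arange(1, design.n_subjects + 1), qs)
    groups = np.where(ids <= design.n_control, CONTROL, TREATMENT)
    records = pd.DataFrame(
        {
            "Y": y,
            "ID": ids,
            "time": np.concatenate(times),
            "group": groups,
            "Y_obs": y.copy(),
        }
    )
    ds = SimulatedDataset(
        records=records,
        mu=mu,
        sigma=sigma,
        n_total=int(sum(qs)),
        miss_data=_empty_miss_data(),
        sampling_modes=modes,
        design=design,
    )
    if induce_missing:
        ds = induce_missingness(ds, design, rng)
    return ds


def simulate_feature(
    design: SimulationDesign, rng: np.random.Generator | None = None
) -> SimulatedDataset:
    """Simulate one feature end to end.

    Composes the timepoint schedule, mean vector, block covariance,
    truncated-MVN draw and missingness induction; the same seed always
    reproduces the identical dataset.
    """
    violations = design.validate()
    if violations:
        raise ValueError("invalid simulation design: " + "; ".join(violations))
    if rng is None:
        rng = design.rng()
    times = make_timepoints(design, rng)
    return _simulate_with_times(design, times, rng)


def simulate_community(
    features: int,
    diff_abun_features: int,
    design: SimulationDesign,
    rng: np.random.Generator | None = None,
) -> CommunityDataset:
    """Simulate a feature-by-sample community table.

    The first ``diff_abun_features`` features carry the design's trend
    (rows Diff_Bug1, Diff_Bug2, ...); the rest are simulated with no
    differential abundance (rows NoDiffBug_1, ...). All features share the
    same sampling schedule and metadata but have independent noise, drawn
    from per-feature substreams of the design seed so each feature is
    individually reproducible.
    """
    if not 0 <= diff_abun_features <= features:
        raise ValueError(
            f"diff_abun_features must be in [0, {features}], got {diff_abun_features}"
        )
    violations = design.validate()
    if violations:
        raise ValueError("invalid simulation design: " + "; ".join(violations))

    streams = np.random.SeedSequence(design.seed).spawn(features + 1)
    schedule_rng = np.random.default_rng(streams[0])
    times = make_timepoints(design, schedule_rng)

    null_design = replace(design, trend=TrendSpec("none"))
    rows, names = [], []
    for k in range(features):
        fd = design if k < diff_abun_features else null_design
        feature_rng = np.random.default_rng(streams[k + 1])
        ds = _simulate_with_times(fd, times, feature_rng)
        rows.append(ds.y_obs)
        if k < diff_abun_features:
            names.append(f"Diff_Bug{k + 1}")
        else:
            names.append(f"NoDiffBug_{k - diff_abun_features + 1}")

    n_samples = sum(len(t) for t in times)
    sample_ids = [f"Sample_{j + 1}" for j in range(n_samples)]
    qs = [len(t) for t in times]
    ids = np.repeat(np.arange(1, design.n_subjects + 1), qs)
    meta = pd.DataFrame(
        {
            "ID": ids,
            "time": np.concatenate(times),
            "group": np.where(ids <= design.n_control, CONTROL, TREATMENT),
            "Sample_ID": sample_ids,
        },
        index=sample_ids,
    )
    abundance = pd.DataFrame(np.vstack(rows), index=names, columns=sample_ids)
    return CommunityDataset(abundance=abundance, sample_meta=meta)


def simulate_from_design(
    sample_design: pd.DataFrame,
    replication_factor: int,
    control_mean: float,
    covariance: CovarianceSpec,
    trend: TrendSpec,
    truncation: TruncationSpec | None = None,
    rng: np.random.Generator | int | None = None,
) -> SimulatedDataset:
    """Simulate from an observed sampling design with subject replication.

    ``sample_design`` is a table with columns ID, time, group giving each
    original subject's measurement schedule (times sorted within subject).
    Every subject's time vector is copied ``replication_factor`` times as
    new subjects with the group preserved, emulating a scaled-up rerun of
    an observed study; the standard mean/covariance/sampling pipeline then
    runs on the (possibly unequal-q) design. Control replicates receive IDs
    1..n0, treatment the remainder.
    """
    required = {"ID", "time", "group"}
    if sample_design is None or len(sample_design) == 0:
        raise ValueError("sample_design table is empty")
    missing_cols = required - set(sample_design.columns)
    if missing_cols:
        raise ValueError(f"sample_design lacks columns: {sorted(missing_cols)}")
    if replication_factor < 1:
        raise ValueError("replication_factor must be >= 1")
    if truncation is None:
        truncation = TruncationSpec()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    subjects = []  # (group, times) per original subject, controls first
    for sid, g in sample_design.groupby("ID", sort=True):
        t = np.asarray(g["time"], dtype=float)
        if t.size == 0:
            raise ValueError(f"subject {sid} has no timepoints")
        if np.any(np.diff(t) < 0):
            raise ValueError(f"times for subject {sid} are not sorted")
        grp = str(g["group"].iloc[0])
        subjects.append((grp, t))
    subjects.sort(key=lambda s: 0 if s[0] == CONTROL else 1)

    times: list[NDArray[np.float64]] = []
    n_control = 0
    for grp, t in subjects:
        for _ in range(replication_factor):
            times.append(t)
            if grp == CONTROL:
                n_control += 1
    n_treat = len(times) - n_control

    all_t = np.concatenate(times)
    t1, tq = float(np.min(all_t)), float(np.max(all_t))
    design = SimulationDesign(
        n_control=max(n_control, 1),
        n_treat=max(n_treat, 1),
        control_mean=control_mean,
        covariance=covariance,
        trend=trend,
        num_timepoints=max(2, max(len(t) for t in times)),
        t_interval=(t1, tq),
        truncation=truncation,
    )
    # overriding n_control/n_treat above only matters for group labelling;
    # the record layout is driven by the per-subject time vectors
    design = replace(design, n_control=n_control, n_treat=n_treat)
    if n_control == 0 or n_treat == 0:
        raise ValueError("sample_design must contain both Control and Treatment subjects")
    return _simulate_with_times(design, times, rng, induce_missing=False)
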