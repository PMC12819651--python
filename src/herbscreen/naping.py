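"""Statistical analysis of nuclear-receptor coregulator binding plates.

The workflow mirrors a fraction-screening campaign against the glucocorticoid
receptor (GR):

1. **Modulation** — per motif, the log2 fold change (LFC) of a condition's
   mean binding versus the unstimulated (Apo) mean, with a Welch two-sample
   t-test wherever both conditions carry technical replicates.  Significance
   tiers are the conventional stars (* p<0.05, ** p<0.01, *** p<0.001).
2. **Motif classification** — motifs significantly modulated by the
   stimulus control (cortisol) are *GC-responsive*; motifs modulated by plant
   fractions but not cortisol are *plant-exclusive*; motifs modulated by both
   are *shared*; the rest *unresponsive*.
3. **Cluster detection** — reverse-phase fractionation spreads each
   metabolite over adjacent fractions, so genuine activity appears as a
   contiguous, bell-shaped LFC gradient across the sequential well order.
   Screening plates carry a single replicate per fraction, so hit finding
   here is threshold- and shape-based, never p-value-based.
4. **Apex confirmation** — the fraction of maximal activity in each cluster
   is retested with replicates and confirmed per-motif by the Welch test.
5. **Competition (spiking)** — adding a soluble motif to the assay competes
   one-to-one for the receptor's coregulator-binding surface; inhibition of
   binding to all responsive immobilized motifs indicates a single shared
   binding conformation.  Calls are "+" (all motifs inhibited), "-" (fewer
   than half) or "±" (in between).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .plates import (
    APO,
    BindingPlate,
    PlateError,
    index_to_well,
    load_plate,
    well_to_index,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ALPHA_TIERS",
    "stars_for",
    "modulation",
    "classify_motifs",
    "ActiveCluster",
    "detect_clusters",
    "ApexConfirmation",
    "confirm_apex",
    "InhibitionCall",
    "inhibition_call",
    "CoregulatorProfileModel",
    "CoregulatorProfileResults",
]

#: Significance tiers for the star annotation, strictly decreasing.
ALPHA_TIERS = (0.05, 0.01, 0.001)

#: Pseudo-count (fluorescence units) guarding log2 of zero means.
EPSILON = 1.0

MOTIF_CLASSES = ("gc_responsive", "plant_exclusive", "shared", "unresponsive")


def stars_for(p: float, tiers: Sequence[float] = ALPHA_TIERS) -> str:
    """Star annotation for a p-value: ns / * / ** / ***."""
    if p is None or np.isnan(p):
        return ""
    if not (len(tiers) == 3 and tiers[0] > tiers[1] > tiers[2] > 0):
        raise ValueError("alpha tiers must be three strictly decreasing levels")
    if p < tiers[2]:
        return "***"
    if p < tiers[1]:
        return "**"
    if p < tiers[0]:
        return "*"
    return "ns"


def _welch_p(a: np.ndarray, b: np.ndarray, alternative: str = "two-sided") -> float:
    """Welch two-sample t-test p-value; NaN when either side is unreplicated."""
    return float(
        _welch_p_rows(
            np.asarray(a, dtype=float)[None, :],
            np.asarray(b, dtype=float)[None, :],
            alternative,
        )[0]
    )


def _welch_p_rows(
    a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"
) -> np.ndarray:
    """Row-wise Welch t-test p-values for two replicate matrices.

    NaN cells are treated as absent replicates; rows with fewer than two
    replicates on either side get a NaN p-value.  Identical constant rows
    give p = 1, distinct constant rows p = 0 (the zero-variance limit).
    """
    import warnings

    na = np.sum(~np.isnan(a), axis=1).astype(float)
    nb = np.sum(~np.isnan(b), axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma, mb = np.nanmean(a, axis=1), np.nanmean(b, axis=1)
        va = np.nanvar(a, axis=1, ddof=1)
        vb = np.nanvar(b, axis=1, ddof=1)
        se2 = va / na + vb / nb
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (
            (va / na) ** 2 / np.maximum(na - 1, 1)
            + (vb / nb) ** 2 / np.maximum(nb - 1, 1)
        )
        if alternative == "two-sided":
            p = 2.0 * stats.t.sf(np.abs(t), df)
        elif alternative == "less":
            p = stats.t.cdf(t, df)
        elif alternative == "greater":
            p = stats.t.sf(t, df)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    # zero-variance limit
    degenerate = se2 == 0
    if np.any(degenerate):
        equal = np.isclose(ma, mb)
        if alternative == "two-sided":
            p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)
        elif alternative == "less":
            p = np.where(degenerate, np.where(equal, 1.0, np.where(ma < mb, 0.0, 1.0)), p)
        else:
            p = np.where(degenerate, np.where(equal, 1.0, np.where(ma > mb, 0.0, 1.0)), p)
    p = np.where((na < 2) | (nb < 2), np.nan, p)
    return p


def modulation(
    plate: BindingPlate,
    condition: str,
    epsilon: float = EPSILON,
    alpha_tiers: Sequence[float] = ALPHA_TIERS,
) -> pd.DataFrame:
    """Per-motif log2 fold change of a condition versus Apo, with Welch tests.

    Returns a frame indexed by motif with columns ``condition, apo_mean,
    mean, lfc, p_value, stars``.  ``lfc = log2(mean(cond)+eps) -
    log2(mean(Apo)+eps)``; it is exactly 0 when the condition mean equals the
    Apo mean.  The p-value is a two-sided Welch t-test on the replicate
    values and is NaN (stars empty) when either side has a single replicate.
    """
    if condition not in plate.conditions:
        raise PlateError(f"condition {condition!r} absent from plate")
    apo = plate.value_matrix(APO)
    cond = plate.value_matrix(condition)
    motifs = [m for m in plate.motifs if m in cond.index and m in apo.index]
    apo_mat = apo.loc[motifs].to_numpy(dtype=float)
    cond_mat = cond.loc[motifs].to_numpy(dtype=float)
    apo_mean = np.nanmean(apo_mat, axis=1)
    cond_mean = np.nanmean(cond_mat, axis=1)
    lfc = np.log2(cond_mean + epsilon) - np.log2(apo_mean + epsilon)
    pvals = _welch_p_rows(cond_mat, apo_mat)
    return pd.DataFrame(
        {
            "condition": condition,
            "apo_mean": apo_mean,
            "mean": cond_mean,
            "lfc": lfc,
            "p_value": pvals,
            "stars": [stars_for(p, alpha_tiers) for p in pvals],
        },
        index=pd.Index(motifs, name="motif"),
    )


def lfc_matrix(
    plate: BindingPlate, conditions: Iterable[str] | None = None, epsilon: float = EPSILON
) -> pd.DataFrame:
    """Motif x condition LFC matrix (fraction conditions by default)."""
    conds = list(conditions) if conditions is not None else list(plate.fraction_conditions)
    means = plate.mean_table()
    apo = means[APO].reindex(list(plate.motifs))
    out = {}
    for c in conds:
        out[c] = np.log2(means[c].reindex(apo.index) + epsilon) - np.log2(apo + epsilon)
    return pd.DataFrame(out)


def _pvalue_matrix(
    plate: BindingPlate, conditions: Sequence[str]
) -> pd.DataFrame:
    """Motif x condition Welch p-values versus Apo (NaN when unreplicated)."""
    apo = plate.value_matrix(APO)
    cols = {}
    for c in conditions:
        cond = plate.value_matrix(c)
        motifs = [m for m in plate.motifs if m in cond.index and m in apo.index]
        cols[c] = pd.Series(
            _welch_p_rows(
                cond.loc[motifs].to_numpy(dtype=float),
                apo.loc[motifs].to_numpy(dtype=float),
            ),
            index=motifs,
        )
    return pd.DataFrame(cols).reindex(list(plate.motifs))


def classify_motifs(
    plate: BindingPlate,
    control: str = "cortisol",
    alpha: float = 0.05,
    lfc_threshold: float = 0.5,
    epsilon: float = EPSILON,
) -> pd.DataFrame:
    """Partition motifs by what modulates them: control GC, fractions, both.

    A motif counts as modulated by the control when the Welch test against
    Apo is significant at ``alpha`` (replicated data) or, on unreplicated
    plates, when ``|LFC|`` reaches ``lfc_threshold``.  Fraction modulation is
    judged the same way across all fraction conditions.  Returns a frame
    indexed by motif with ``motif_class``, the control LFC / fold change /
    p-value, and the count of active fractions.
    """
    if control not in plate.conditions:
        raise PlateError(f"control condition {control!r} absent from plate")
    if not plate.fraction_conditions:
        raise PlateError("plate has no fraction conditions to classify against")
    ctrl = modulation(plate, control, epsilon)
    ctrl_active = np.where(
        np.isnan(ctrl["p_value"]),
        np.abs(ctrl["lfc"]) >= lfc_threshold,
        (ctrl["p_value"] < alpha) & (np.abs(ctrl["lfc"]) >= lfc_threshold),
    )
    frac_lfc = lfc_matrix(plate, epsilon=epsilon).loc[ctrl.index]
    frac_reps = {c: plate.n_replicates(c) for c in plate.fraction_conditions}
    if min(frac_reps.values()) >= 2 and plate.n_replicates(APO) >= 2:
        frac_p = _pvalue_matrix(plate, plate.fraction_conditions).loc[ctrl.index]
        frac_active_any = (
            ((frac_p < alpha) & (np.abs(frac_lfc) >= lfc_threshold))
            .any(axis=1)
            .to_numpy()
        )
    else:
        frac_active_any = (np.abs(frac_lfc) >= lfc_threshold).any(axis=1).to_numpy()
    n_active = (np.abs(frac_lfc) >= lfc_threshold).sum(axis=1).to_numpy()
    cls = np.select(
        [
            ctrl_active & frac_active_any,
            ctrl_active,
            frac_active_any,
        ],
        ["shared", "gc_responsive", "plant_exclusive"],
        default="unresponsive",
    )
    return pd.DataFrame(
        {
            "motif_class": cls,
            "control_lfc": ctrl["lfc"],
            "control_fold": 2.0 ** ctrl["lfc"],
            "control_p": ctrl["p_value"],
            "n_active_fractions": n_active,
            "max_abs_fraction_lfc": np.abs(frac_lfc).max(axis=1),
        },
        index=ctrl.index,
    )


# ---------------------------------------------------------------------------
# Cluster detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActiveCluster:
    """A contiguous run of fractions with a unimodal activity gradient.

    Indices are 1-based sequential fraction indices (row-major well order),
    inclusive.  ``motifs`` are the plant-responsive motifs whose runs merged
    into this cluster; ``motif_signs`` records each motif's LFC direction at
    the apex, used later to check confirmation in the expected direction.
    ``profile`` is the per-fraction mean LFC over the motif set.
    """

    plant_id: str
    motifs: tuple[str, ...]
    start_index: int
    end_index: int
    apex_index: int
    profile: pd.Series = field(repr=False, compare=False)
    motif_signs: Mapping[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.start_index <= self.apex_index <= self.end_index:
            raise ValueError("apex must lie within the cluster span")

    @property
    def length(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def apex_well(self) -> str:
        return index_to_well(self.apex_index)

    @property
    def span_wells(self) -> str:
        return f"{index_to_well(self.start_index)}-{index_to_well(self.end_index)}"


def unimodality_violations(profile: np.ndarray) -> int:
    """Minimum number of sign violations against a rise-then-fall shape.

    For every candidate peak position the successive differences before it
    should be non-negative and after it non-positive; zero differences are
    neutral.  The returned minimum over peak positions is 0 for an exactly
    bell-shaped profile.
    """
    d = np.diff(np.asarray(profile, dtype=float))
    if d.size == 0:
        return 0
    neg = np.concatenate([[0], np.cumsum(d < 0)])  # falls before split
    pos = np.concatenate([[0], np.cumsum(d > 0)])  # rises up to split
    viol = neg[:-1] + (pos[-1] - pos[:-1])  # split before each diff
    viol = np.append(viol, neg[-1])  # split after all diffs
    return int(viol.min())


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) positional indices, inclusive."""
    out: list[tuple[int, int]] = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(mask) - 1))
    return out


def detect_clusters(
    plate: BindingPlate,
    min_len: int = 3,
    lfc_threshold: float = 0.5,
    unimodality_tolerance: int = 1,
    motifs: Iterable[str] | None = None,
    control: str = "cortisol",
    alpha: float = 0.05,
    epsilon: float = EPSILON,
) -> tuple[ActiveCluster, ...]:
    """Find bell-shaped active fraction clusters on plant-responsive motifs.

    For each eligible motif (plant-exclusive and shared motifs by default,
    or an explicit ``motifs`` list), maximal contiguous runs of fractions
    with ``|LFC| >= lfc_threshold`` are extracted; runs of length
    ``>= min_len`` whose ``|LFC|`` profile rises then falls (at most
    ``unimodality_tolerance`` sign violations) are kept.  Overlapping runs
    from different motifs merge into one :class:`ActiveCluster`; the apex is
    the fraction maximizing the mean ``|LFC|`` over the cluster's motif set.
    A plate without qualifying runs yields an empty tuple.
    """
    fracs = plate.fraction_conditions
    if not fracs:
        return ()
    if motifs is None:
        if control in plate.conditions:
            classes = classify_motifs(plate, control, alpha, lfc_threshold, epsilon)
            eligible = [
                m
                for m in plate.motifs
                if classes.loc[m, "motif_class"] in ("plant_exclusive", "shared")
            ]
        else:
            eligible = list(plate.motifs)
    else:
        eligible = [m for m in motifs if m in plate.motifs]
    if not eligible:
        return ()
    lfc = lfc_matrix(plate, epsilon=epsilon)
    index_of = {well_to_index(c): c for c in fracs}  # sequential index -> well
    # Work on the fixed 1..96 grid so run contiguity is contiguity in the
    # fractionation sequence even when some wells are missing from the plate.
    runs_by_motif: list[tuple[str, int, int]] = []  # (motif, start idx, end idx)
    for m in eligible:
        grid = np.zeros(96)
        for i, c in index_of.items():
            grid[i - 1] = lfc.loc[m, c]
        mask = np.abs(grid) >= lfc_threshold
        for s, e in _runs(mask):
            if e - s + 1 < min_len:
                continue
            if unimodality_violations(np.abs(grid[s : e + 1])) <= unimodality_tolerance:
                runs_by_motif.append((m, s + 1, e + 1))
    if not runs_by_motif:
        return ()
    # Merge overlapping runs (in sequential-index space) into clusters.
    runs_sorted = sorted(runs_by_motif, key=lambda t: (t[1], t[2]))
    merged: list[dict] = []
    for m, si, ei in runs_sorted:
        if merged and si <= merged[-1]["end"]:
            merged[-1]["end"] = max(merged[-1]["end"], ei)
            merged[-1]["motifs"].add(m)
        else:
            merged.append({"start": si, "end": ei, "motifs": {m}})
    clusters: list[ActiveCluster] = []
    for grp in merged:
        span = [i for i in range(grp["start"], grp["end"] + 1) if i in index_of]
        cols = [index_of[i] for i in span]
        sub = lfc.loc[sorted(grp["motifs"]), cols]
        mean_abs = np.abs(sub.to_numpy(dtype=float)).mean(axis=0)
        apex_pos = int(np.argmax(mean_abs))
        apex_idx = span[apex_pos]
        signs = {
            m: int(np.sign(sub.loc[m, cols[apex_pos]]) or 1) for m in sub.index
        }
        profile = pd.Series(
            sub.mean(axis=0).to_numpy(dtype=float),
            index=pd.Index(span, name="fraction_index"),
            name="mean_lfc",
        )
        clusters.append(
            ActiveCluster(
                plant_id=plate.plant_id,
                motifs=tuple(sorted(grp["motifs"])),
                start_index=grp["start"],
                end_index=grp["end"],
                apex_index=apex_idx,
                profile=profile,
                motif_signs=signs,
            )
        )
    return tuple(clusters)


# ---------------------------------------------------------------------------
# Confirmation and competition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ApexConfirmation:
    """Replicated retest of a cluster's apex fraction."""

    cluster: ActiveCluster
    results: pd.DataFrame = field(repr=False)
    confirmed: bool


def confirm_apex(
    plate_confirmation: BindingPlate,
    cluster: ActiveCluster,
    alpha: float = 0.05,
    epsilon: float = EPSILON,
) -> ApexConfirmation:
    """Statistically confirm a cluster's apex on a replicated plate.

    The apex fraction must be present with at least two technical replicates.
    The cluster is confirmed iff at least one of its motifs is significantly
    modulated versus Apo at ``alpha``, in the direction seen on the screening
    plate.
    """
    apex = cluster.apex_well
    if apex not in plate_confirmation.conditions:
        raise PlateError(
            f"apex fraction {apex!r} absent from confirmation plate"
        )
    if plate_confirmation.n_replicates(apex) < 2:
        raise PlateError(f"apex fraction {apex!r} is not replicated")
    res = modulation(plate_confirmation, apex, epsilon)
    res = res.loc[[m for m in cluster.motifs if m in res.index]]
    expected = np.array([cluster.motif_signs.get(m, 1) for m in res.index])
    ok = (res["p_value"].to_numpy() < alpha) & (
        np.sign(res["lfc"].to_numpy()) == expected
    )
    return ApexConfirmation(cluster=cluster, results=res, confirmed=bool(ok.any()))


@dataclass(frozen=True)
class InhibitionCall:
    """Outcome of a one-to-one competition (spiking) experiment.

    ``call`` is "+" when every responsive motif shows significantly reduced
    binding under spiking, "-" when fewer than half do, and "±" otherwise
    (the reduced proportion lies in ``[0.5, 1)`` by default).
    """

    plant_id: str
    fraction: str
    spiked_motif: str
    call: str
    outcomes: pd.DataFrame = field(repr=False, compare=False)

    @property
    def reduced_proportion(self) -> float:
        return float(self.outcomes["reduced"].mean())


def inhibition_call(
    activity_plate: BindingPlate,
    spiked_plate: BindingPlate,
    stimulus: str,
    spiked_motif: str,
    alpha: float = 0.05,
    responsive_motifs: Iterable[str] | None = None,
    partial_band: tuple[float, float] = (0.5, 1.0),
    lfc_threshold: float = 0.5,
    epsilon: float = EPSILON,
) -> InhibitionCall:
    """Classify competitive inhibition of stimulus-responsive motifs.

    ``responsive_motifs`` defaults to the motifs whose binding the stimulus
    significantly *increases* on the activity plate (Welch test at ``alpha``
    when replicated, else ``LFC >= lfc_threshold``).  Each responsive motif
    is then tested one-sidedly for reduced binding in the spiked condition
    ``"<stimulus>+<spiked_motif>"`` versus the unspiked stimulus on the
    spiked plate.
    """
    spiked_cond = f"{stimulus}+{spiked_motif}"
    if spiked_cond not in spiked_plate.conditions:
        raise PlateError(f"spiked condition {spiked_cond!r} absent from plate")
    if stimulus not in spiked_plate.conditions:
        raise PlateError(f"stimulus {stimulus!r} absent from spiked plate")
    if responsive_motifs is None:
        # Responsive = materially induced (LFC at threshold) and, where
        # replicates allow, significantly so; the effect-size gate keeps
        # noise-significant motifs from diluting the competition call.
        act = modulation(activity_plate, stimulus, epsilon)
        sig = np.where(
            np.isnan(act["p_value"]),
            act["lfc"] >= lfc_threshold,
            (act["p_value"] < alpha) & (act["lfc"] >= lfc_threshold),
        )
        responsive = [m for m, s in zip(act.index, sig) if s]
    else:
        responsive = [m for m in responsive_motifs if m in spiked_plate.motifs]
    if not responsive:
        raise PlateError("nothing to inhibit: no responsive motifs")
    rows = []
    for m in responsive:
        un = spiked_plate.values(m, stimulus)
        sp = spiked_plate.values(m, spiked_cond)
        p = _welch_p(sp, un, alternative="less")
        lfc = float(np.log2(sp.mean() + epsilon) - np.log2(un.mean() + epsilon))
        reduced = bool(p < alpha) if not np.isnan(p) else bool(lfc <= -lfc_threshold)
        rows.append((m, lfc, p, reduced))
    outcomes = pd.DataFrame(
        rows, columns=["motif", "lfc_spiked", "p_one_sided", "reduced"]
    ).set_index("motif")
    prop = float(outcomes["reduced"].mean())
    lo, hi = partial_band
    if prop >= hi:
        call = "+"
    elif prop < lo:
        call = "-"
    else:
        call = "±"
    return InhibitionCall(
        plant_id=spiked_plate.plant_id,
        fraction=stimulus,
        spiked_motif=spiked_motif,
        call=call,
        outcomes=outcomes,
    )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class CoregulatorProfileModel:
    """Coregulator binding-profile analysis for one plant's fraction series.

    Parameters
    ----------
    plate
        The screening plate (Apo + control + sequential fractions).
    control
        Name of the GC stimulus control condition (default ``"cortisol"``).
    alpha, alpha_tiers
        Hit-calling significance level and the star tiers.
    lfc_threshold, min_len, unimodality_tolerance
        Cluster-detection settings: minimum ``|LFC|``, minimum run length and
        permitted shape violations.
    partial_band
        Reduced-motif proportion band reported as "±" in competition calls.
    """

    def __init__(
        self,
        plate: BindingPlate,
        control: str = "cortisol",
        alpha: float = 0.05,
        alpha_tiers: Sequence[float] = ALPHA_TIERS,
        lfc_threshold: float = 0.5,
        min_len: int = 3,
        unimodality_tolerance: int = 1,
        partial_band: tuple[float, float] = (0.5, 1.0),
        epsilon: float = EPSILON,
    ):
        if list(alpha_tiers) != sorted(alpha_tiers, reverse=True) or min(alpha_tiers) <= 0:
            raise ValueError("alpha_tiers must be strictly decreasing and positive")
        if lfc_threshold <= 0 or min_len < 1:
            raise ValueError("thresholds must be positive")
        self.plate = plate
        self.control = control
        self.alpha = float(alpha)
        self.alpha_tiers = tuple(alpha_tiers)
        self.lfc_threshold = float(lfc_threshold)
        self.min_len = int(min_len)
        self.unimodality_tolerance = int(unimodality_tolerance)
        self.partial_band = tuple(partial_band)
        self.epsilon = float(epsilon)

    @classmethod
    def from_file(cls, path: str | Path, **kwargs) -> "CoregulatorProfileModel":
        return cls(load_plate(path), **kwargs)

    def fit(self) -> "CoregulatorProfileResults":
        """Run modulation, classification and cluster detection."""
        control_mod = (
            modulation(self.plate, self.control, self.epsilon, self.alpha_tiers)
            if self.control in self.plate.conditions
            else None
        )
        classes = (
            classify_motifs(
                self.plate, self.control, self.alpha, self.lfc_threshold, self.epsilon
            )
            if control_mod is not None and self.plate.fraction_conditions
            else None
        )
        fractions = lfc_matrix(self.plate, epsilon=self.epsilon)
        eligible = None
        if classes is not None:
            eligible = [
                m
                for m in self.plate.motifs
                if classes.loc[m, "motif_class"] in ("plant_exclusive", "shared")
            ]
        clusters = detect_clusters(
            self.plate,
            min_len=self.min_len,
            lfc_threshold=self.lfc_threshold,
            unimodality_tolerance=self.unimodality_tolerance,
            motifs=eligible,
            control=self.control,
            alpha=self.alpha,
            epsilon=self.epsilon,
        )
        return CoregulatorProfileResults(
            model=self,
            control_modulation=control_mod,
            motif_classes=classes,
            fraction_lfc=fractions,
            clusters=clusters,
        )


@dataclass
class CoregulatorProfileResults:
    """Results of :meth:`CoregulatorProfileModel.fit`."""

    model: CoregulatorProfileModel
    control_modulation: pd.DataFrame | None
    motif_classes: pd.DataFrame | None
    fraction_lfc: pd.DataFrame
    clusters: tuple[ActiveCluster, ...]

    @property
    def plant_id(self) -> str:
        return self.model.plate.plant_id

    def class_counts(self) -> dict[str, int]:
        if self.motif_classes is None:
            return {}
        vc = self.motif_classes["motif_class"].value_counts()
        return {c: int(vc.get(c, 0)) for c in MOTIF_CLASSES}

    def total_cluster_fractions(self) -> int:
        return sum(c.length for c in self.clusters)

    def confirm(
        self, confirmation_plate: BindingPlate
    ) -> tuple[ApexConfirmation, ...]:
        """Confirm every detected cluster's apex on a replicated plate."""
        return tuple(
            confirm_apex(confirmation_plate, c, self.model.alpha, self.model.epsilon)
            for c in self.clusters
        )

    def inhibition(
        self,
        spiked_plate: BindingPlate,
        stimulus: str,
        spiked_motif: str,
        responsive_motifs: Iterable[str] | None = None,
    ) -> InhibitionCall:
        """Competition call for one apex fraction (see :func:`inhibition_call`)."""
        return inhibition_call(
            self.model.plate if responsive_motifs is None else spiked_plate,
            spiked_plate,
            stimulus,
            spiked_motif,
            alpha=self.model.alpha,
            responsive_motifs=responsive_motifs,
            partial_band=self.model.partial_band,
            lfc_threshold=self.model.lfc_threshold,
            epsilon=self.model.epsilon,
        )

    def clusters_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plant_id": [c.plant_id for c in self.clusters],
                "motifs": ["|".join(c.motifs) for c in self.clusters],
                "start": [c.start_index for c in self.clusters],
                "apex": [c.apex_index for c in self.clusters],
                "end": [c.end_index for c in self.clusters],
                "apex_well": [c.apex_well for c in self.clusters],
                "span_wells": [c.span_wells for c in self.clusters],
                "length": [c.length for c in self.clusters],
            }
        )

    @staticmethod
    def calls_frame(calls: Iterable[InhibitionCall]) -> pd.DataFrame:
        """Summary table of competition calls (plant, fraction, motif, call)."""
        calls = list(calls)
        return pd.DataFrame(
            {
                "plant": [c.plant_id for c in calls],
                "fraction_position": [c.fraction for c in calls],
                "activity": [c.call for c in calls],
                "motif": [c.spiked_motif for c in calls],
                "inhibition": [c.call for c in calls],
            }
        )

    def summary(self) -> str:
        cc = self.class_counts()
        lines = [
            f"Coregulator binding profile — plant {self.plant_id!r}",
            "=" * 60,
            f"motifs:                 {len(self.model.plate.motifs)}",
            f"fraction conditions:    {len(self.model.plate.fraction_conditions)}",
            f"|LFC| threshold:        {self.model.lfc_threshold}",
        ]
        if cc:
            lines.append("motif classes:")
            for c in MOTIF_CLASSES:
                lines.append(f"  {c:<20} {cc[c]}")
        lines.append(f"active clusters:        {len(self.clusters)}")
        for c in self.clusters:
            lines.append(
                f"  {c.span_wells} (apex {c.apex_well}, {c.length} fractions, "
                f"motifs: {', '.join(c.motifs)})"
            )
        lines.append(f"fractions in clusters:  {self.total_cluster_fractions()}")
        return "\n".join(lines)

    def run_summary(self) -> dict:
        return {
            "plant_id": self.plant_id,
            "n_motifs": len(self.model.plate.motifs),
            "n_fractions": len(self.model.plate.fraction_conditions),
            "class_counts": self.class_counts(),
            "n_clusters": len(self.clusters),
            "cluster_spans": [c.span_wells for c in self.clusters],
            "cluster_apexes": [c.apex_well for c in self.clusters],
            "n_cluster_fractions": self.total_cluster_fractions(),
        }

    def save(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: dict[str, Path] = {}
        if self.control_modulation is not None:
            p = outdir / f"{self.plant_id}_control_modulation.csv"
            self.control_modulation.to_csv(p)
            written["control_modulation"] = p
        if self.motif_classes is not None:
            p = outdir / f"{self.plant_id}_motif_classes.csv"
            self.motif_classes.to_csv(p)
            written["motif_classes"] = p
        p = outdir / f"{self.plant_id}_fraction_lfc.csv"
        self.fraction_lfc.to_csv(p)
        written["fraction_lfc"] = p
        p = outdir / f"{self.plant_id}_clusters.csv"
        self.clusters_frame().to_csv(p, index=False)
        written["clusters"] = p
        return written

    def plot_profile(self, motif: str, ax=None):
        """LFC across sequential fractions for one motif, clusters shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        fracs = list(self.fraction_lfc.columns)
        xs = [well_to_index(c) for c in fracs]
        ax.plot(xs, self.fraction_lfc.loc[motif, fracs], marker=".", lw=1)
        ax.axhline(0, color="grey", lw=0.8)
        for thr in (self.model.lfc_threshold, -self.model.lfc_threshold):
            ax.axhline(thr, color="grey", lw=0.8, ls=":")
        for c in self.clusters:
            if motif in c.motifs:
                ax.axvspan(c.start_index - 0.5, c.end_index + 0.5, alpha=0.15)
        ax.set_xlabel("fraction index (row-major well order)")
        ax.set_ylabel("LFC vs Apo")
        ax.set_title(f"{self.plant_id}: {motif}")
        return ax
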