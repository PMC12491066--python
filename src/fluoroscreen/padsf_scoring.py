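"""Melt-curve scoring, replicate aggregation and hit triage for dye screens.

The screen looks for dyes whose fluorescence is high at the start of the
thermal ramp (indicating binding to the fibril) and decays as heating
disrupts the binding site.  Each well/channel curve is reduced to four
statistics -- raw maximum, raw minimum, temperature of the maximum, and the
amplitude of the control-subtracted curve -- and a rule table maps those
statistics to an integer score in {0, 1, 3, 5, 8, 10}.  Scores from two
biological replicates are summed (cumulative maximum 20); dyes reaching the
cumulative cutoff against at least one fibril sample become hits unless they
also score against the monomeric-protein counter-screen.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .plate_io import MeltCurve, ScreenRun, ValidationError, Well

logger = logging.getLogger("fluoroscreen")

#: The only values the scoring rule table can emit.
SCORE_VALUES = (0, 1, 3, 5, 8, 10)


@dataclass(frozen=True)
class CurveSummary:
    """The four statistics the scoring rules consume.

    ``f_max``, ``f_min`` and ``t_at_max`` come from the raw sample curve;
    ``delta_f`` is the amplitude (max minus min) of the control-subtracted
    curve.  All fluorescence values are in RFU, temperatures in degC.
    """

    f_max: float
    f_min: float
    t_at_max: float
    delta_f: float


@dataclass(frozen=True)
class ScoringThresholds:
    """The rule-table boundaries, exposed so alternates can be configured.

    Defaults are the published screening thresholds.  "Between A and B"
    band bounds are read so the rules partition without holes against the
    neighboring strict inequalities: the 8-rule's delta_f band is
    [1500, 2500] (closed at 2500, since the 10-rule requires strictly more
    than 2500) while the 5-rule's is [1000, 1500); the 3-rule's temperature
    band is [55, 70] (t exactly 70 matches the 3-rule, not the 1-rule, which
    requires strictly more than 70).
    """

    f_max_low: float = 1000.0
    f_max_high: float = 2000.0
    f_min_tight: float = -1000.0
    f_min_loose: float = -2000.0
    delta_top: float = 2500.0
    delta_mid: float = 1500.0
    delta_low: float = 1000.0
    delta_late: float = 2000.0
    t_early: float = 55.0
    t_late: float = 70.0


DEFAULT_THRESHOLDS = ScoringThresholds()


# ---------------------------------------------------------------------------
# Curve -> summary -> score
# ---------------------------------------------------------------------------

def subtract_control(sample: MeltCurve, control: MeltCurve) -> MeltCurve:
    """Pointwise sample minus control on a shared temperature grid."""
    if sample.channel.name != control.channel.name:
        raise ValidationError(
            f"channel mismatch: sample {sample.channel.name!r} vs "
            f"control {control.channel.name!r}"
        )
    if sample.temperatures_c.shape != control.temperatures_c.shape or not np.allclose(
        sample.temperatures_c, control.temperatures_c, atol=1e-6
    ):
        raise ValidationError(
            f"temperature grid mismatch between sample "
            f"({sample.temperatures_c[0]}-{sample.temperatures_c[-1]} degC, "
            f"{len(sample)} pts) and control "
            f"({control.temperatures_c[0]}-{control.temperatures_c[-1]} degC, "
            f"{len(control)} pts) in channel {sample.channel.name}"
        )
    return MeltCurve(sample.temperatures_c.copy(), sample.rfu - control.rfu, sample.channel)


def summarize_curve(
    sample: MeltCurve,
    control: MeltCurve,
    *,
    delta_mode: str = "range",
) -> CurveSummary:
    """Reduce a raw curve plus its subtraction control to a :class:`CurveSummary`.

    ``f_max``/``f_min``/``t_at_max`` are read from the raw sample curve; the
    subtracted curve contributes only ``delta_f``.  Ties in the maximum are
    resolved to the lowest temperature.

    Parameters
    ----------
    delta_mode : {"range", "max"}
        ``"range"`` (default) takes delta_f as max - min of the subtracted
        curve (the standard DSF amplitude reading); ``"max"`` takes the
        maximum of the subtracted curve instead.
    """
    if not (np.all(np.isfinite(sample.rfu)) and np.all(np.isfinite(control.rfu))):
        bad = np.flatnonzero(~np.isfinite(sample.rfu))
        where = (
            f"temperature {sample.temperatures_c[bad[0]]} degC" if bad.size else "control curve"
        )
        raise ValidationError(
            f"non-finite fluorescence in channel {sample.channel.name} at {where}"
        )
    diff = subtract_control(sample, control)
    i_max = int(np.argmax(sample.rfu))  # argmax returns the first (lowest-T) maximum
    if delta_mode == "range":
        delta = float(diff.rfu.max() - diff.rfu.min())
    elif delta_mode == "max":
        delta = float(diff.rfu.max())
    else:
        raise ValueError(f"unknown delta_mode {delta_mode!r}")
    return CurveSummary(
        f_max=float(sample.rfu.max()),
        f_min=float(sample.rfu.min()),
        t_at_max=float(sample.temperatures_c[i_max]),
        delta_f=delta,
    )


def score_summary(s: CurveSummary, thresholds: ScoringThresholds = DEFAULT_THRESHOLDS) -> int:
    """Apply the published rule table to a curve summary.

    Rules are evaluated in descending score order; the first match wins and
    every finite summary receives exactly one score from
    ``{10, 8, 5, 3, 1, 0}``.
    """
    th = thresholds
    early = s.t_at_max < th.t_early
    if s.f_max > th.f_max_low and s.f_min > th.f_min_tight and s.delta_f > th.delta_top and early:
        return 10
    if (
        s.f_max > th.f_max_low
        and s.f_min > th.f_min_loose
        and th.delta_mid <= s.delta_f <= th.delta_top
        and early
    ):
        return 8
    if (
        s.f_max > th.f_max_low
        and s.f_min > th.f_min_loose
        and th.delta_low <= s.delta_f < th.delta_mid
        and early
    ):
        return 5
    if (
        s.f_max > th.f_max_high
        and s.f_min > th.f_min_loose
        and s.delta_f > th.delta_late
        and th.t_early <= s.t_at_max <= th.t_late
    ):
        return 3
    if (
        s.f_max > th.f_max_high
        and s.f_min > th.f_min_loose
        and s.delta_f > th.delta_late
        and s.t_at_max > th.t_late
    ):
        return 1
    return 0


# ---------------------------------------------------------------------------
# Wells and runs
# ---------------------------------------------------------------------------

@dataclass
class WellScore:
    """Per-channel scores for one well plus the max-over-channels well score."""

    dye_id: str
    sample_id: str
    channel_scores: dict[str, int]
    well_score: int
    best_channel: str


@dataclass
class ScoreTable:
    """Scores for one replicate: (dye_id, sample_id) -> :class:`WellScore`."""

    replicate_index: int
    entries: dict[tuple[str, str], WellScore] = field(default_factory=dict)

    def well_score(self, dye_id: str, sample_id: str) -> int:
        return self.entries[(dye_id, sample_id)].well_score

    def dyes(self) -> set[str]:
        return {dye for dye, _ in self.entries}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (dye, sample), ws in sorted(self.entries.items()):
            for channel, score in sorted(ws.channel_scores.items()):
                rows.append({
                    "dye_id": dye, "sample_id": sample,
                    "replicate": self.replicate_index,
                    "channel": channel, "score": score,
                    "well_score": ws.well_score,
                })
        return pd.DataFrame(rows)


@dataclass
class AdditiveScoreTable:
    """Cumulative two-replicate scores: (dye_id, sample_id) -> 0..20."""

    entries: dict[tuple[str, str], int] = field(default_factory=dict)

    def best_for_dye(self, dye_id: str) -> tuple[str, int]:
        pairs = [(s, v) for (d, s), v in self.entries.items() if d == dye_id]
        if not pairs:
            raise KeyError(dye_id)
        sample, value = max(pairs, key=lambda p: (p[1], p[0]))
        return sample, value

    def to_matrix(self) -> pd.DataFrame:
        """Dye x sample matrix view (missing combinations filled with 0)."""
        if not self.entries:
            raise ValidationError("empty additive score table")
        df = pd.Series(self.entries).unstack(fill_value=0)
        return df.sort_index(axis=0).sort_index(axis=1)


def find_subtraction_control(well: Well, controls: ScreenRun, channel: str) -> MeltCurve:
    """Locate the matched control curve for a well/channel.

    Fibril wells subtract the polyanion-only control sharing their dye and
    inducer; monomer wells subtract the dye-alone (no-protein) control.
    """
    if well.sample_type == "fibril":
        wanted_type = "polyanion_only"
        candidates = [
            c for c in controls.wells
            if c.sample_type == wanted_type and c.dye_id == well.dye_id
            and c.inducer_id == well.inducer_id
        ]
    elif well.sample_type == "monomer":
        wanted_type = "no_protein"
        candidates = [
            c for c in controls.wells
            if c.sample_type == wanted_type and c.dye_id == well.dye_id
        ]
    else:
        raise ValidationError(
            f"well ({well.dye_id}, {well.sample_id}) of type {well.sample_type!r} "
            f"is itself a control and is not scored"
        )
    for c in candidates:
        if channel in c.curves:
            return c.curves[channel]
    raise ValidationError(
        f"no matched {wanted_type} control for ({well.dye_id}, {well.sample_id}, "
        f"channel {channel})"
    )


def score_well(
    well: Well,
    controls: ScreenRun,
    thresholds: ScoringThresholds = DEFAULT_THRESHOLDS,
    *,
    delta_mode: str = "range",
) -> WellScore:
    """Score every channel of a well; the well score is the channel maximum.

    Hits surface in different channels for different dyes, so the winning
    channel is recorded alongside the score.
    """
    channel_scores: dict[str, int] = {}
    for channel, curve in well.curves.items():
        control = find_subtraction_control(well, controls, channel)
        summary = summarize_curve(curve, control, delta_mode=delta_mode)
        channel_scores[channel] = score_summary(summary, thresholds)
    if not channel_scores:
        raise ValidationError(f"well ({well.dye_id}, {well.sample_id}) has no curves")
    best_channel = max(sorted(channel_scores), key=lambda ch: channel_scores[ch])
    return WellScore(
        well.dye_id, well.sample_id, channel_scores,
        channel_scores[best_channel], best_channel,
    )


def score_run(
    run: ScreenRun,
    controls: ScreenRun,
    thresholds: ScoringThresholds = DEFAULT_THRESHOLDS,
    sample_types: Sequence[str] = ("fibril", "monomer"),
) -> ScoreTable:
    """Score all fibril and monomer-counter-screen wells of one replicate."""
    table = ScoreTable(run.replicate_index)
    for well in run.wells:
        if well.sample_type not in sample_types:
            continue
        table.entries[(well.dye_id, well.sample_id)] = score_well(well, controls, thresholds)
    return table


def flag_bright_wells(controls: ScreenRun, rfu_cutoff: float = 1000.0) -> list[str]:
    """Dyes whose dye-alone control already exceeds ``rfu_cutoff`` at ramp start.

    Intrinsically bright dyes are the most common false-positive artefact:
    small pipetting differences produce large apparent RFU differences.  They
    are flagged for manual inspection, never auto-removed.
    """
    flagged = []
    for well in controls.wells_of_type("no_protein"):
        if any(curve.rfu[0] > rfu_cutoff for curve in well.curves.values()):
            flagged.append(well.dye_id)
    return sorted(set(flagged))


# ---------------------------------------------------------------------------
# Replicates and triage
# ---------------------------------------------------------------------------

def aggregate_replicates(r1: ScoreTable, r2: ScoreTable) -> AdditiveScoreTable:
    """Entrywise sum of two replicate well scores (symmetric; max 20)."""
    k1, k2 = set(r1.entries), set(r2.entries)
    if k1 != k2:
        asym = sorted(k1 ^ k2)
        raise ValidationError(f"replicates cover different (dye, sample) keys: {asym}")
    return AdditiveScoreTable({
        key: r1.entries[key].well_score + r2.entries[key].well_score for key in k1
    })


@dataclass
class HitRecord:
    """Triage outcome for one dye."""

    dye_id: str
    supporting_samples: list[str]
    additive_score: int
    monomer_flag: bool = False
    curated: bool = False


@dataclass
class TriageResult:
    """Hits plus the monomer-reactive dyes excluded on the way.

    ``hits`` never contains a record with ``monomer_flag=True``; excluded
    records are kept so the audit trail of the counter-screen is explicit.
    """

    hits: list[HitRecord]
    excluded: list[HitRecord]

    def __iter__(self):
        return iter(self.hits)


def _monomer_score(dye_id: str, monomer_tables: Sequence[ScoreTable]) -> int:
    scores = [
        ws.well_score
        for table in monomer_tables
        for (dye, _sample), ws in table.entries.items()
        if dye == dye_id
    ]
    if not scores:
        raise ValidationError(f"dye {dye_id!r} missing from the monomer score table")
    return max(scores)


def triage_hits(
    additive: AdditiveScoreTable,
    monomer_scores: ScoreTable | Sequence[ScoreTable],
    hit_cutoff: int = 20,
    monomer_cutoff: int = 5,
    curated_additions: Sequence[str] = (),
) -> TriageResult:
    """Select hits from the cumulative score table, applying the monomer filter.

    A dye qualifies when its best additive score over samples reaches
    ``hit_cutoff``; a qualified dye is excluded (``monomer_flag=True``) when
    its monomeric-protein counter-screen well score reaches
    ``monomer_cutoff`` in either replicate.  ``curated_additions`` are
    manually rescued dyes appended with ``curated=True`` and subjected to the
    same monomer filter -- curation criteria are editorial and never
    inferred.
    """
    if isinstance(monomer_scores, ScoreTable):
        monomer_tables: Sequence[ScoreTable] = (monomer_scores,)
    else:
        monomer_tables = tuple(monomer_scores)
    hits: list[HitRecord] = []
    excluded: list[HitRecord] = []
    dyes = sorted({dye for dye, _ in additive.entries})
    for dye in dyes:
        mono = _monomer_score(dye, monomer_tables)
        supporting = sorted(
            s for (d, s), v in additive.entries.items() if d == dye and v >= hit_cutoff
        )
        best = max(v for (d, _s), v in additive.entries.items() if d == dye)
        if not supporting:
            continue
        record = HitRecord(dye, supporting, best, monomer_flag=mono >= monomer_cutoff)
        (excluded if record.monomer_flag else hits).append(record)
    for dye in curated_additions:
        if any(h.dye_id == dye for h in hits):
            continue
        mono = _monomer_score(dye, monomer_tables)
        supporting = sorted(s for (d, s) in additive.entries if d == dye)
        best = max(
            (v for (d, _s), v in additive.entries.items() if d == dye), default=0
        )
        record = HitRecord(dye, supporting, best, monomer_flag=mono >= monomer_cutoff,
                           curated=True)
        (excluded if record.monomer_flag else hits).append(record)
    return TriageResult(hits, excluded)


def hit_rate(n_hits: int, n_library: int) -> float:
    """Percentage of the library that hit, rounded half-up to one decimal.

    Exact rational arithmetic (no binary-float rounding surprises):
    100 * n_hits / n_library, half-up at the first decimal.
    """
    if n_library <= 0:
        raise ValidationError("n_library must be positive")
    if not 0 <= n_hits <= n_library:
        raise ValidationError("n_hits must lie in [0, n_library]")
    tenths = Fraction(1000 * n_hits, n_library)
    rounded_tenths = math.floor(tenths + Fraction(1, 2))
    return rounded_tenths / 10.0


def sd_activity_call(
    fibril_signals: Sequence[float],
    monomer_signals: Sequence[float],
    k: float = 3.0,
) -> bool:
    """Plate-reader activity rule: fibril mean >= monomer mean + k * monomer s.d.

    The boundary is inclusive ("at least k standard deviations").  Used for
    the abbreviated screens where endpoint fluorescence replaces the full
    melt ramp.
    """
    monomer = np.asarray(monomer_signals, dtype=float)
    fibril = np.asarray(fibril_signals, dtype=float)
    if monomer.size < 2:
        raise ValidationError("need >= 2 monomer replicates to estimate the s.d.")
    sd = float(monomer.std(ddof=1))
    if sd == 0.0:
        raise ValidationError(
            "monomer replicates have zero variance; supply an explicit tolerance "
            "instead of a multiple of the s.d."
        )
    return bool(fibril.mean() >= monomer.mean() + k * sd)


# ---------------------------------------------------------------------------
# Heatmap ordering
# ---------------------------------------------------------------------------

def cluster_order(additive: AdditiveScoreTable) -> tuple[list[str], list[str]]:
    """Row (dye) and column (sample) orders for the clustered score heatmap.

    Agglomerative clustering with average linkage on Euclidean distances,
    applied independently to rows and columns of the dye x sample additive
    score matrix.  Identifiers are pre-sorted so the ordering is
    deterministic under ties.
    """
    matrix = additive.to_matrix()

    def _order(m: np.ndarray, ids: list[str]) -> list[str]:
        if len(ids) == 1:
            return ids
        link = linkage(m, method="average", metric="euclidean")
        return [ids[i] for i in leaves_list(link)]

    rows = _order(matrix.to_numpy(dtype=float), list(matrix.index))
    cols = _order(matrix.to_numpy(dtype=float).T, list(matrix.columns))
    return rows, cols


def plot_score_clustermap(additive: AdditiveScoreTable, path=None):
    """Render the clustered additive-score heatmap (average linkage, Euclidean)."""
    import seaborn as sns

    matrix = additive.to_matrix()
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValidationError("clustermap needs at least a 2x2 score matrix")
    grid = sns.clustermap(matrix, method="average", metric="euclidean", cmap="viridis")
    if path is not None:
        grid.savefig(path)
    return grid
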