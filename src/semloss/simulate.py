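"""Synthetic PPA-like cohort generation.

Each participant is driven by two latent traits drawn per profile: semantic
integrity ``s`` (probability of spontaneously naming an item) and general
cognition ``g`` (MMSE success probability).  Cue retrieval and word-picture
matching are conditionally independent Bernoulli outcomes per item, and ROI
uptake ratios are linear in the latents plus Gaussian noise, so recovery of
the coupling can be tested end to end with the scoring and statistics
modules.  Profile defaults are tuned so the three stock profiles land near
group mean SSL scores of roughly 0.29 / 0.51 / 0.69; they are tuning
targets, not ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvariantViolationError
from .scoring import ItemOutcomes, ParticipantRecord

N_ITEMS = 64
MMSE_MAX = 30

ROI_NAMES = ("atl_left", "atl_right", "dlpfc_left", "dlpfc_right")


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters for one simulated deficit profile.

    ``p_name`` is the latent ``s`` itself (monotone identity link); ``s`` and
    ``g`` are normal draws clipped to [0, 1].  ATL ratios couple to ``s``
    (atl = atl_beta0 + atl_beta1·s + noise) and dlPFC ratios to ``g``.
    """

    label: str
    s_mean: float
    s_sd: float
    g_mean: float
    g_sd: float
    p_cue_given_miss: float
    p_wpmt_given_miss: float
    p_wpmt_given_hit: float = 0.98
    atl_beta0: float = 0.70
    atl_beta1: float = 0.50
    dlpfc_gamma0: float = 0.70
    dlpfc_gamma1: float = 0.40
    roi_sigma: float = 0.05

    def __post_init__(self):
        for name in ("p_cue_given_miss", "p_wpmt_given_miss", "p_wpmt_given_hit"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvariantViolationError(f"{name} must be in [0, 1]")
        if self.s_sd < 0 or self.g_sd < 0:
            raise InvariantViolationError("latent SDs must be non-negative")
        if self.roi_sigma < 0:
            raise InvariantViolationError("roi_sigma must be non-negative")


def default_profiles() -> list[GroupProfile]:
    """Stock storage-like / intermediate / processing-like profiles."""
    return [
        GroupProfile(
            label="storage-like",
            s_mean=0.20, s_sd=0.08,
            g_mean=0.55, g_sd=0.10,
            p_cue_given_miss=0.20,
            p_wpmt_given_miss=0.40,
        ),
        GroupProfile(
            label="intermediate",
            s_mean=0.45, s_sd=0.10,
            g_mean=0.50, g_sd=0.10,
            p_cue_given_miss=0.50,
            p_wpmt_given_miss=0.55,
        ),
        GroupProfile(
            label="processing-like",
            s_mean=0.65, s_sd=0.10,
            g_mean=0.60, g_sd=0.10,
            p_cue_given_miss=0.75,
            p_wpmt_given_miss=0.85,
        ),
    ]


@dataclass(frozen=True)
class SimulatedCohort:
    participants: tuple[tuple[ItemOutcomes, ParticipantRecord], ...]
    profiles: tuple[tuple[GroupProfile, int], ...]
    seed: int

    @property
    def records(self) -> list[ParticipantRecord]:
        return [rec for _, rec in self.participants]

    @property
    def items(self) -> list[ItemOutcomes]:
        return [it for it, _ in self.participants]


def simulate_participant(
    profile: GroupProfile,
    rng: np.random.Generator,
    participant_id: str = "sim-000",
) -> tuple[ItemOutcomes, ParticipantRecord]:
    """Draw one participant: 64 item triples, MMSE, and coupled ROI ratios."""
    s = float(np.clip(rng.normal(profile.s_mean, profile.s_sd), 0.0, 1.0))
    g = float(np.clip(rng.normal(profile.g_mean, profile.g_sd), 0.0, 1.0))

    named = rng.random(N_ITEMS) < s
    cued = (~named) & (rng.random(N_ITEMS) < profile.p_cue_given_miss)
    p_recog = np.where(named, profile.p_wpmt_given_hit, profile.p_wpmt_given_miss)
    recognized = rng.random(N_ITEMS) < p_recog
    mmse = int(rng.binomial(MMSE_MAX, g))

    roi = {}
    for side in ("left", "right"):
        atl = profile.atl_beta0 + profile.atl_beta1 * s
        dlpfc = profile.dlpfc_gamma0 + profile.dlpfc_gamma1 * g
        if profile.roi_sigma > 0:
            atl += rng.normal(0.0, profile.roi_sigma)
            dlpfc += rng.normal(0.0, profile.roi_sigma)
        roi[f"atl_{side}"] = max(atl, 1e-6)
        roi[f"dlpfc_{side}"] = max(dlpfc, 1e-6)

    items = ItemOutcomes(
        participant_id=participant_id,
        group_label=profile.label,
        named_spontaneously=tuple(bool(v) for v in named),
        named_with_cue=tuple(bool(v) for v in cued),
        recognized_in_wpmt=tuple(bool(v) for v in recognized),
        mmse=mmse,
    )
    record = items.to_record(roi_ratios=roi)
    return items, record


def simulate_cohort(
    profiles: list[tuple[GroupProfile, int]], seed: int
) -> SimulatedCohort:
    """Simulate n participants per profile, bit-reproducible under the seed.

    One root seed sequence per cohort; each participant gets a deterministic
    spawned substream, so per-participant draws do not interact.
    """
    labels = [p.label for p, _ in profiles]
    if len(set(labels)) != len(labels):
        raise InvariantViolationError("duplicate profile labels")
    for _, n in profiles:
        if n < 1:
            raise InvariantViolationError("need n >= 1 per profile")

    root = np.random.SeedSequence(seed)
    total = sum(n for _, n in profiles)
    streams = root.spawn(total)

    out = []
    idx = 0
    for profile, n in profiles:
        for i in range(n):
            rng = np.random.default_rng(streams[idx])
            pid = f"{profile.label}-{i:03d}"
            out.append(simulate_participant(profile, rng, participant_id=pid))
            idx += 1
    return SimulatedCohort(
        participants=tuple(out),
        profiles=tuple((p, n) for p, n in profiles),
        seed=seed,
    )
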