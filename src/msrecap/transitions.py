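"""Age-specific transition blocks for the four-state model.

States are ordered 0: non-breeder at N, 1: non-breeder at R, 2: breeder at
N, 3: breeder at R, 4: dead.  Death is carried as an explicit absorbing
fifth state so that every block is exactly row-stochastic; the live 4x4
upper-left corner matches the field parameterisation, with the dead column
absorbing one minus the row's survival.

Three block kinds cover a female's life:

* juvenile (age 0 -> 1): first-year survival, natal dispersal ``n`` and the
  first-year breeding probability ``alpha_1``;
* immature (attained age a in 2..4): adult survival, breeding dispersal
  ``b`` and ``alpha_a``, with ``alpha_4 = 1`` forcing all survivors into
  the breeder states;
* experienced (attained age >= 5, and all adult-marked females): breeder
  rows only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ADULT, JUVENILE, CaptureHistory, StudyDesign

N_STATES = 5
DEAD = 4


class RateError(ValueError):
    """A demographic rate lies outside [0, 1] or violates a structural fix."""


@dataclass
class RateSet:
    """Resolved demographic rates on the probability scale.

    Array shapes (S species, C = 2 colonies, I intervals, T occasions):

    * ``phi_juv``, ``phi_ad``: (S, C, I) apparent survival;
    * ``alpha``: (4, S, C, I, 2) probability a not-yet-breeding female
      starts to breed at attained age 1..4, by colony of settlement,
      interval and birth-cohort pulse flag; the age-4 slice is 1;
    * ``natal``, ``breeding``: (S, 2) dispersal, directions [N->R, R->N];
    * ``p``: (S, C, 2, T) recapture by status (0 = not yet bred,
      1 = experienced breeder); 0 at occasion 0 and at skipped occasions.
    """

    phi_juv: np.ndarray
    phi_ad: np.ndarray
    alpha: np.ndarray
    natal: np.ndarray
    breeding: np.ndarray
    p: np.ndarray
    validate: bool = True

    def __post_init__(self):
        for f in ("phi_juv", "phi_ad", "alpha", "natal", "breeding", "p"):
            setattr(self, f, np.asarray(getattr(self, f), dtype=float))
        if self.validate:
            self._check()

    def _check(self):
        for f in ("phi_juv", "phi_ad", "alpha", "natal", "breeding", "p"):
            a = getattr(self, f)
            if np.any((a < 0) | (a > 1)) or np.any(np.isnan(a)):
                raise RateError(f"{f} has entries outside [0, 1]")
        if not np.allclose(self.alpha[3], 1.0):
            raise RateError("alpha at attained age 4 must be 1 (forced breeding)")

    @property
    def n_species(self) -> int:
        return self.phi_juv.shape[0]

    @property
    def n_intervals(self) -> int:
        return self.phi_juv.shape[2]

    def p_vector(self, s: int, occ: int) -> np.ndarray:
        """Recapture over live states (nb-N, nb-R, br-N, br-R) at occasion occ."""
        return np.array(
            [
                self.p[s, 0, 0, occ],
                self.p[s, 1, 0, occ],
                self.p[s, 0, 1, occ],
                self.p[s, 1, 1, occ],
            ]
        )

    @classmethod
    def constant(
        cls,
        design: StudyDesign,
        phi_juv,
        phi_ad,
        alpha1,
        alpha2,
        alpha3,
        natal_NR,
        natal_RN,
        breeding_NR,
        breeding_RN,
        p,
    ) -> "RateSet":
        """Time-constant rates; scalars apply to all species, sequences are
        per-species.  Recapture is zeroed at occasion 0 and skipped occasions.
        """
        S, T = len(design.species), design.n_occasions
        I = T - 1

        def per_species(x):
            return np.broadcast_to(np.asarray(x, dtype=float), (S,))

        pj, pa = per_species(phi_juv), per_species(phi_ad)
        a1, a2, a3 = per_species(alpha1), per_species(alpha2), per_species(alpha3)
        nNR, nRN = per_species(natal_NR), per_species(natal_RN)
        bNR, bRN = per_species(breeding_NR), per_species(breeding_RN)
        pp = per_species(p)

        alpha = np.zeros((4, S, 2, I, 2))
        for s in range(S):
            alpha[0, s] = a1[s]
            alpha[1, s] = a2[s]
            alpha[2, s] = a3[s]
        alpha[3] = 1.0
        parr = np.zeros((S, 2, 2, T))
        for occ in range(1, T):
            if not design.is_skipped(occ):
                parr[:, :, :, occ] = pp[:, None, None]
        return cls(
            phi_juv=np.broadcast_to(pj[:, None, None], (S, 2, I)).copy(),
            phi_ad=np.broadcast_to(pa[:, None, None], (S, 2, I)).copy(),
            alpha=alpha,
            natal=np.stack([nNR, nRN], axis=1),
            breeding=np.stack([bNR, bRN], axis=1),
            p=parr,
        )


@dataclass
class TransitionBlock:
    """One interval's 5x5 transition matrix and live-state recapture vector."""

    matrix: np.ndarray
    recapture: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.recapture = np.asarray(self.recapture, dtype=float)


def _finish(live: np.ndarray) -> np.ndarray:
    """Append the absorbing dead column/row to a 4x4 live block."""
    M = np.zeros((N_STATES, N_STATES))
    M[:4, :4] = live
    M[:4, DEAD] = 1.0 - live.sum(axis=1)
    M[DEAD, DEAD] = 1.0
    return M


def juvenile_matrix(phi_N, phi_R, n_NR, n_RN, a1_N, a1_R) -> np.ndarray:
    """Age 0 -> 1 transition matrix (rows 3-4 unreachable, sent to dead)."""
    _check_unit(phi_N, phi_R, n_NR, n_RN, a1_N, a1_R)
    live = np.zeros((4, 4))
    live[0] = [
        phi_N * (1 - n_NR) * (1 - a1_N),
        phi_N * n_NR * (1 - a1_R),
        phi_N * (1 - n_NR) * a1_N,
        phi_N * n_NR * a1_R,
    ]
    live[1] = [
        phi_R * n_RN * (1 - a1_N),
        phi_R * (1 - n_RN) * (1 - a1_R),
        phi_R * n_RN * a1_N,
        phi_R * (1 - n_RN) * a1_R,
    ]
    return _finish(live)


def immature_matrix(phi_N, phi_R, b_NR, b_RN, a_N, a_R) -> np.ndarray:
    """Attained-age 2..4 transition matrix (alpha applied to rows 1-2 only)."""
    _check_unit(phi_N, phi_R, b_NR, b_RN, a_N, a_R)
    live = np.zeros((4, 4))
    live[0] = [
        phi_N * (1 - b_NR) * (1 - a_N),
        phi_N * b_NR * (1 - a_R),
        phi_N * (1 - b_NR) * a_N,
        phi_N * b_NR * a_R,
    ]
    live[1] = [
        phi_R * b_RN * (1 - a_N),
        phi_R * (1 - b_RN) * (1 - a_R),
        phi_R * b_RN * a_N,
        phi_R * (1 - b_RN) * a_R,
    ]
    live[2] = [0.0, 0.0, phi_N * (1 - b_NR), phi_N * b_NR]
    live[3] = [0.0, 0.0, phi_R * b_RN, phi_R * (1 - b_RN)]
    return _finish(live)


def experienced_matrix(phi_N, phi_R, b_NR, b_RN) -> np.ndarray:
    """Attained-age >= 5 (and adult-marked) transition matrix."""
    _check_unit(phi_N, phi_R, b_NR, b_RN)
    live = np.zeros((4, 4))
    live[2] = [0.0, 0.0, phi_N * (1 - b_NR), phi_N * b_NR]
    live[3] = [0.0, 0.0, phi_R * b_RN, phi_R * (1 - b_RN)]
    return _finish(live)


def _check_unit(*vals):
    for v in vals:
        if not 0.0 <= float(v) <= 1.0:
            raise RateError(f"rate {v} outside [0, 1]")


# ---------------------------------------------------------------------------
# block builders against a RateSet
# ---------------------------------------------------------------------------

def juvenile_block(rates: RateSet, s: int, interval: int, cohort: int = 0) -> TransitionBlock:
    M = juvenile_matrix(
        rates.phi_juv[s, 0, interval],
        rates.phi_juv[s, 1, interval],
        rates.natal[s, 0],
        rates.natal[s, 1],
        rates.alpha[0, s, 0, interval, cohort],
        rates.alpha[0, s, 1, interval, cohort],
    )
    return TransitionBlock(M, rates.p_vector(s, interval + 1))


def immature_block(
    rates: RateSet, attained_age: int, s: int, interval: int, cohort: int = 0
) -> TransitionBlock:
    if not 2 <= attained_age <= 4:
        raise ValueError("immature blocks cover attained ages 2..4")
    M = immature_matrix(
        rates.phi_ad[s, 0, interval],
        rates.phi_ad[s, 1, interval],
        rates.breeding[s, 0],
        rates.breeding[s, 1],
        rates.alpha[attained_age - 1, s, 0, interval, cohort],
        rates.alpha[attained_age - 1, s, 1, interval, cohort],
    )
    return TransitionBlock(M, rates.p_vector(s, interval + 1))


def experienced_block(rates: RateSet, s: int, interval: int) -> TransitionBlock:
    M = experienced_matrix(
        rates.phi_ad[s, 0, interval],
        rates.phi_ad[s, 1, interval],
        rates.breeding[s, 0],
        rates.breeding[s, 1],
    )
    return TransitionBlock(M, rates.p_vector(s, interval + 1))


def block_kind(age_at_marking: str, release: int, interval: int):
    """Which block applies to interval t -> t+1 for a given female.

    Returns ``('juv', 1)``, ``('imm', a)`` with attained age a in 2..4, or
    ``('exp', None)``.
    """
    if interval < release:
        raise ValueError("interval precedes release")
    if age_at_marking == ADULT:
        return ("exp", None)
    attained = interval - release + 1
    if attained == 1:
        return ("juv", 1)
    if attained <= 4:
        return ("imm", attained)
    return ("exp", None)


def block_for(
    history: CaptureHistory,
    rates: RateSet,
    design: StudyDesign,
    interval: int,
) -> TransitionBlock:
    """Transition block for one female over occasions interval -> interval+1."""
    s = design.species.index(history.species)
    release = history.release_occasion
    cohort = 0
    if history.age_at_marking == JUVENILE:
        cohort = design.cockchafer_flag(design.occasion_labels[release])
    kind, a = block_kind(history.age_at_marking, release, interval)
    if kind == "juv":
        return juvenile_block(rates, s, interval, cohort)
    if kind == "imm":
        return immature_block(rates, a, s, interval, cohort)
    return experienced_block(rates, s, interval)
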