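"""Individual-based diploid Wright-Fisher forward simulator.

Two execution paths implement the same update rule (non-overlapping
generations, random hermaphroditic mating with selfing permitted, parents
drawn with probability proportional to fitness, multiplicative fitness across
sites with dominance ``h``):

* :func:`run_replicate` executes a whole replicate through a compiled kernel
  (sparse haplotype representation; see ``_kernel.py``) — this is the
  production path.
* :func:`compute_fitness`, :func:`make_gamete` and :func:`step_generation`
  are pure-Python reference operations on a small :class:`PopulationState`,
  convenient for inspecting single transitions and for validating the kernel.

:func:`run_single_locus_sweep` simulates only the selected locus of the same
diploid model and serves as an independent oracle for sweep dynamics.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .models import ModelSpec

__all__ = [
    "MCLASS_NAMES",
    "MutationRecord",
    "PopulationState",
    "ReplicateResult",
    "SampleHaplotypes",
    "EngineError",
    "FitnessError",
    "compute_fitness",
    "make_gamete",
    "step_generation",
    "run_replicate",
    "run_single_locus_sweep",
    "sample_to_ms",
    "records_to_tsv",
]

MCLASS_NAMES = ("neutral", "beneficial", "deleterious", "sweep")
MCLASS_CODES = {name: i for i, name in enumerate(MCLASS_NAMES)}
FATE_NAMES = ("segregating", "fixed", "lost")


class EngineError(RuntimeError):
    pass


class FitnessError(EngineError):
    """Raised when the population reaches infinite or all-zero fitness.

    At large scaling factors the stacking of Q-multiplied selection
    coefficients can overflow the multiplicative fitness ("infinite
    fitness"), the practical failure mode of aggressively rescaled runs.
    """


# ---------------------------------------------------------------------------
# Pure-Python reference operations
# ---------------------------------------------------------------------------

@dataclass
class MutationRecord:
    id: int
    position: int
    mclass: str
    s: float
    origin_generation: int
    post_burn_in: bool = True
    fate: str = "segregating"
    fixation_generation: Optional[int] = None


@dataclass
class PopulationState:
    """A population as 2*N haplotypes, each a position-sorted array of mutation ids."""

    generation: int
    N_current: int
    haplotypes: list  # list of np.ndarray of mutation ids
    mutations: dict = field(default_factory=dict)  # id -> MutationRecord
    substitutions: set = field(default_factory=set)
    next_id: int = 0

    @classmethod
    def empty(cls, N: int) -> "PopulationState":
        return cls(generation=0, N_current=N,
                   haplotypes=[np.empty(0, dtype=np.int64) for _ in range(2 * N)])

    def allele_frequency(self, mid: int) -> float:
        carriers = sum(1 for hap in self.haplotypes if mid in hap)
        return carriers / len(self.haplotypes)


def compute_fitness(individual: tuple, records: dict, h: float) -> float:
    """Multiplicative fitness of a diploid: (1+s) per homozygous site, (1+h*s)
    per heterozygous site; each factor clamped to >= 0 (a lethal genotype
    zeroes the product)."""
    hap_a, hap_b = individual
    set_a, set_b = set(map(int, hap_a)), set(map(int, hap_b))
    w = 1.0
    for mid in set_a | set_b:
        s = records[mid].s if isinstance(records[mid], MutationRecord) else records[mid]
        if s == 0.0:
            continue
        factor = (1.0 + s) if (mid in set_a and mid in set_b) else (1.0 + h * s)
        w *= max(factor, 0.0)
    if not np.isfinite(w):
        raise FitnessError("infinite fitness: multiplicative fitness overflowed "
                           "(selection coefficients too large, e.g. at high Q)")
    return max(w, 0.0)


def _draw_class(mix, rng) -> str:
    u = rng.random()
    if u < mix.f_n:
        return "neutral"
    if u < mix.f_n + mix.f_b:
        return "beneficial"
    return "deleterious"


def make_gamete(parent: tuple, model: ModelSpec, state: PopulationState,
                rng: np.random.Generator) -> np.ndarray:
    """Recombine the parent's two haplotypes and superimpose new mutations.

    Crossover count ~ Poisson(r*(L-1)) with breakpoints uniform on [1, L-1];
    segments alternate between the parental haplotypes starting from a fair
    coin.  New mutations ~ Poisson(mu*L) at uniform positions not currently
    segregating, with class drawn from the mix and s from the class DFE.
    New mutations are registered in ``state.mutations``.
    """
    hap_a, hap_b = parent
    pos_of = {mid: state.mutations[mid].position for mid in list(hap_a) + list(hap_b)}
    k = rng.poisson(model.r * (model.L - 1)) if model.r > 0 else 0
    side = int(rng.random() < 0.5)
    if k == 0:
        gamete = list(hap_a if side == 0 else hap_b)
    else:
        bps = np.sort(rng.integers(1, model.L, size=k))
        merged = []
        for src, hap in enumerate((hap_a, hap_b)):
            for mid in hap:
                pos = pos_of[mid]
                segment = int(np.searchsorted(bps, pos, side="right"))
                hom = mid in set(hap_a) and mid in set(hap_b)
                if hom:
                    if src == 0:  # transmitted regardless of phase; count once
                        merged.append((pos, mid))
                elif (side + segment) % 2 == src:
                    merged.append((pos, mid))
        merged.sort()
        gamete = [mid for _, mid in merged]

    n_new = rng.poisson(model.mu * model.L) if model.mu > 0 else 0
    if n_new == 0:
        return np.asarray(gamete, dtype=np.int64)
    occupied = {rec.position for rec in state.mutations.values() if rec.fate == "segregating"}
    for _ in range(n_new):
        pos = int(rng.integers(0, model.L))
        while pos in occupied:
            pos = int(rng.integers(0, model.L))
        occupied.add(pos)
        mclass = _draw_class(model.mix, rng)
        s = float(model.dfe_for(mclass).draw(rng))
        rec = MutationRecord(id=state.next_id, position=pos, mclass=mclass, s=s,
                             origin_generation=state.generation + 1)
        state.mutations[rec.id] = rec
        state.next_id += 1
        gamete.append(rec.id)
    gamete.sort(key=lambda mid: state.mutations[mid].position)
    return np.asarray(gamete, dtype=np.int64)


def step_generation(state: PopulationState, model: ModelSpec,
                    rng: np.random.Generator,
                    N_next: Optional[int] = None) -> PopulationState:
    """Advance one Wright-Fisher generation.

    Each of the ``N_next`` offspring draws two parents independently with
    probability proportional to fitness and receives one gamete from each.
    Mutations present in all 2*N haplotypes become substitutions; mutations
    present in none are marked lost.
    """
    N_next = state.N_current if N_next is None else N_next
    weights = np.array([
        compute_fitness((state.haplotypes[2 * i], state.haplotypes[2 * i + 1]),
                        state.mutations, model.h)
        for i in range(state.N_current)
    ])
    total = weights.sum()
    if total <= 0:
        raise FitnessError("all individuals have zero fitness")
    probs = weights / total

    new_state = PopulationState(
        generation=state.generation + 1, N_current=N_next, haplotypes=[],
        mutations=state.mutations, substitutions=set(state.substitutions),
        next_id=state.next_id)
    uniform = np.allclose(weights, weights[0])
    for _ in range(N_next):
        if uniform:
            p1, p2 = rng.integers(0, state.N_current, size=2)
        else:
            p1, p2 = rng.choice(state.N_current, size=2, p=probs)
        for parent_idx in (p1, p2):
            parent = (state.haplotypes[2 * parent_idx], state.haplotypes[2 * parent_idx + 1])
            new_state.haplotypes.append(make_gamete(parent, model, new_state, rng))
    state.next_id = new_state.next_id  # ids were assigned via new_state

    counts: dict[int, int] = {}
    for hap in new_state.haplotypes:
        for mid in hap:
            counts[int(mid)] = counts.get(int(mid), 0) + 1
    two_n = 2 * N_next
    fixed_ids = {mid for mid, c in counts.items() if c == two_n}
    for mid, rec in new_state.mutations.items():
        if rec.fate != "segregating":
            continue
        if mid in fixed_ids:
            rec.fate = "fixed"
            rec.fixation_generation = new_state.generation
            new_state.substitutions.add(mid)
        elif counts.get(mid, 0) == 0:
            rec.fate = "lost"
    if fixed_ids:
        new_state.haplotypes = [
            np.asarray([m for m in hap if int(m) not in fixed_ids], dtype=np.int64)
            for hap in new_state.haplotypes
        ]
    return new_state


# ---------------------------------------------------------------------------
# Replicate runner (compiled path)
# ---------------------------------------------------------------------------

@dataclass
class SampleHaplotypes:
    """End-of-run haplotype sample: genotype matrix over population-segregating sites."""

    n_individuals: int
    L: int
    positions: np.ndarray  # (S,) int64
    mclass: np.ndarray     # (S,) int8 codes into MCLASS_NAMES
    s: np.ndarray          # (S,) float64
    matrix: np.ndarray     # (2*n_individuals, S) uint8


@dataclass
class ReplicateResult:
    """Outcome of one simulation run.

    ``records`` holds one row per mutation that arose after the burn-in
    (columns: position, mclass, s, origin_generation, fate,
    fixation_generation); ``fixation_times`` are Q-corrected sojourn times
    ``(fixation_generation - origin_generation) * Q`` in unscaled generations.
    Counters are indexed by class code (neutral, beneficial, deleterious,
    sweep) and cover post-burn-in mutations only.
    """

    model: ModelSpec
    Q: float
    seed: int
    sample: SampleHaplotypes
    records: dict
    arisen: np.ndarray
    fixed: np.ndarray
    lost: np.ndarray
    fixation_classes: np.ndarray   # int8 class codes, one per fixation event
    fixation_times: np.ndarray     # float64 corrected times, parallel
    final_generation: int
    sweep_attempts: int = 0

    def fixation_times_for(self, mclass: str) -> np.ndarray:
        code = MCLASS_CODES[mclass]
        return self.fixation_times[self.fixation_classes == code]


_STATUS_MESSAGES = {
    _kernel.STATUS_ZERO_FITNESS: "all individuals have zero fitness",
    _kernel.STATUS_INFINITE_FITNESS: (
        "infinite fitness: multiplicative fitness overflowed (selection "
        "coefficients too large, e.g. at high Q)"),
    _kernel.STATUS_SWEEP_CAP: "conditional sweep failed to fix within the generation cap",
}


def _dfe_arrays(model: ModelSpec):
    kinds = np.zeros(3, dtype=np.int64)
    p1 = np.zeros(3, dtype=np.float64)
    p2 = np.zeros(3, dtype=np.float64)
    sign = np.zeros(3, dtype=np.float64)
    for i, name in enumerate(("neutral", "beneficial", "deleterious")):
        dfe = model.dfe_for(name)
        if dfe.kind == "neutral":
            kinds[i] = _kernel.K_NEUTRAL
        elif dfe.kind == "fixed":
            kinds[i] = _kernel.K_FIXED
            p1[i] = dfe.s_fixed
        elif dfe.kind == "gamma":
            kinds[i] = _kernel.K_GAMMA
            p1[i] = dfe.gamma_mean
            p2[i] = dfe.gamma_shape
        else:
            kinds[i] = _kernel.K_LOGNORMAL
            p1[i] = dfe.lognorm_mu
            p2[i] = dfe.lognorm_sigma
            sign[i] = dfe.sign
    return kinds, p1, p2, sign


def run_replicate(model: ModelSpec, seed: int, *,
                  sample_n: int = 100,
                  recording_override: Optional[int] = None,
                  max_sweep_attempts: int = 100_000) -> ReplicateResult:
    """Run one replicate of ``model`` (already rescaled if Q > 1).

    The burn-in runs first (its mutations are excluded from all statistics),
    followed by the recording span — or, for sweep models, until the
    introduced beneficial fixes (restarting on loss when conditioned).  The
    result is deterministic given ``(model, seed)``.  ``recording_override``
    replaces the recording span, e.g. to extend the window when an
    uncensored fixation-fraction estimate is needed.
    """
    demo = model.demography
    rec_gens = demo.recording_generations if recording_override is None else int(recording_override)
    kinds, p1, p2, sign = _dfe_arrays(model)

    # capacity heuristics; the kernel reports overflow and we retry larger
    theta_tot = 4.0 * demo.N_anc * model.mu * model.L
    hcap = max(64, int(8 * theta_tot) + 64)
    scap = max(1024, int(64 * theta_tot) + 1024)
    influx = 2.0 * max(demo.N_anc, demo.N_post) * model.mu * model.L
    span = rec_gens if not model.sweep.enabled else 60 * demo.N_post
    rcap = max(4096, int(1.3 * influx * max(span, 1)) + 4096)

    sweep_gen_cap = 200 * max(demo.N_anc, demo.N_post)

    for _ in range(8):
        out = _kernel._run_wf_kernel(
            int(seed),
            int(demo.N_anc), int(demo.N_post), int(demo.burn_in_generations), int(rec_gens),
            int(model.L), float(model.mu), float(model.r), float(model.h),
            float(model.mix.f_n), float(model.mix.f_b),
            kinds, p1, p2, sign,
            1 if model.sweep.enabled else 0,
            float(model.sweep.s_sweep),
            int(model.sweep_position),
            1 if model.sweep.condition_on_fixation else 0,
            int(sample_n), int(hcap), int(scap), int(rcap),
            int(sweep_gen_cap), int(max_sweep_attempts))
        status = out[0]
        if status == _kernel.STATUS_HAP_CAPACITY:
            hcap *= 2
            continue
        if status == _kernel.STATUS_SITE_CAPACITY:
            scap *= 2
            continue
        if status == _kernel.STATUS_RECORD_CAPACITY:
            rcap *= 2
            continue
        break

    (status, t_final, attempts, nrec,
     rpos, rclass, rs, rorigin, rfate, rfix,
     arisen, nfixed, nlost,
     got_n, sm_pos, sm_class, sm_s, matrix) = out

    if status != _kernel.STATUS_OK:
        msg = f"replicate seed={seed}: " + _STATUS_MESSAGES.get(
            status, f"engine abort (status {status})")
        if status in (_kernel.STATUS_ZERO_FITNESS, _kernel.STATUS_INFINITE_FITNESS):
            raise FitnessError(msg)
        raise EngineError(msg)

    Q = float(model.Q_applied)
    is_fixed = rfate == _kernel.FIXED
    fix_classes = rclass[is_fixed].copy()
    fix_times = (rfix[is_fixed] - rorigin[is_fixed]).astype(np.float64) * Q

    sample = SampleHaplotypes(
        n_individuals=int(got_n), L=model.L,
        positions=sm_pos, mclass=sm_class, s=sm_s, matrix=matrix)
    records = {
        "position": rpos, "mclass": rclass, "s": rs,
        "origin_generation": rorigin, "fate": rfate, "fixation_generation": rfix,
    }
    return ReplicateResult(
        model=model, Q=Q, seed=int(seed), sample=sample, records=records,
        arisen=np.asarray(arisen), fixed=np.asarray(nfixed), lost=np.asarray(nlost),
        fixation_classes=fix_classes, fixation_times=fix_times,
        final_generation=int(t_final), sweep_attempts=int(attempts))


# ---------------------------------------------------------------------------
# Single-locus sweep oracle
# ---------------------------------------------------------------------------

def run_single_locus_sweep(N: int, s: float, h: float, seed) -> int:
    """Generations from introduction to fixation of one beneficial copy.

    Simulates only the selected locus of the diploid Wright-Fisher model:
    each offspring's two gametes come from independent parents chosen with
    probability proportional to fitness (w_AA = 1+s, w_Aa = 1+h*s, w_aa = 1),
    so offspring genotype counts are multinomial with Hardy-Weinberg
    probabilities at the fitness-weighted gamete frequency.  The mutation is
    re-introduced from scratch whenever it is lost (conditioning on
    fixation).
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if s <= -1:
        raise ValueError("s must be > -1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w_AA, w_Aa, w_aa = 1.0 + s, 1.0 + h * s, 1.0
    while True:
        # one copy: a single heterozygote
        n_AA, n_Aa = 0, 1
        gens = 0
        while True:
            copies = 2 * n_AA + n_Aa
            if copies == 0 or copies == 2 * N:
                break
            n_aa = N - n_AA - n_Aa
            tot = n_AA * w_AA + n_Aa * w_Aa + n_aa * w_aa
            pi = (n_AA * w_AA + 0.5 * n_Aa * w_Aa) / tot
            n_AA = int(rng.binomial(N, pi * pi))
            rest = N - n_AA
            if rest > 0 and pi < 1.0:
                p_het = 2.0 * pi * (1.0 - pi) / (1.0 - pi * pi)
                n_Aa = int(rng.binomial(rest, min(p_het, 1.0)))
            else:
                n_Aa = 0
            gens += 1
        if copies == 2 * N:
            return gens
        # lost: restart


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def sample_to_ms(sample: SampleHaplotypes) -> str:
    """Render the end-of-run sample as an ms-style block
    (segsites / positions on [0,1) / one 0-1 row per haplotype)."""
    order = np.argsort(sample.positions, kind="stable")
    pos = sample.positions[order]
    mat = sample.matrix[:, order]
    buf = io.StringIO()
    buf.write("//\n")
    buf.write(f"segsites: {len(pos)}\n")
    buf.write("positions: " + " ".join(f"{p / sample.L:.6f}" for p in pos) + "\n")
    for row in mat:
        buf.write("".join("1" if v else "0" for v in row) + "\n")
    return buf.getvalue()


def records_to_tsv(result: ReplicateResult, path=None) -> Optional[str]:
    """Mutation records as TSV (id, position, class, s, origin, fate, fixation time)."""
    rec = result.records
    df = pd.DataFrame({
        "id": np.arange(len(rec["position"])),
        "position": rec["position"],
        "mclass": [MCLASS_NAMES[c] for c in rec["mclass"]],
        "s": rec["s"],
        "origin_generation": rec["origin_generation"],
        "fate": [FATE_NAMES[f] for f in rec["fate"]],
        "fixation_generation": rec["fixation_generation"],
    })
    if path is None:
        return df.to_csv(sep="\t", index=False)
    df.to_csv(path, sep="\t", index=False)
    return None
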