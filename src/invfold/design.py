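"""Constrained sequence sampling from the encoder-decoder model.

Decoding proceeds slot by slot: fixed positions are decoded first (they
contribute sequence context but are never re-predicted), tied positions
form joint slots whose member logits are combined into a single
distribution, and the remaining positions are visited in a uniformly random
order.  Temperature scales logits before the softmax, so the T -> 0 limit
is greedy argmax decoding.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import nn
from .alphabet import AA_TO_INDEX, ALPHABET, tokens_to_seq
from .backbone import BackboneStructure
from .errors import ConstraintError
from .features import featurize
from .model import (GraphBatch, ModelConfig, ModelParams, attend_from_ranks,
                    decode_logits, encode)
from .seeds import substream, substream_seed

__all__ = [
    "DesignConstraints",
    "DecodingOrder",
    "SampleResult",
    "DesignResult",
    "parse_constraints",
    "sample_decoding_order",
    "combine_tied_logits",
    "sample_sequence",
    "sample_multistate",
    "tying_from_symmetry",
]


@dataclasses.dataclass
class DesignConstraints:
    """User-facing design constraints.

    fixed: 0-based position -> amino-acid letter (kept, decoded first).
    tied_groups: list of groups, each a list of (position, coefficient);
    members share one sampled letter, drawn from the coefficient-combined
    logits.  omit: letters never sampled (X always).  tie_mode selects
    between combining logits before the softmax ("logits", default) or
    averaging member probability distributions ("probs").

    refine_sweeps: optional conditional-resampling passes after the initial
    decode.  Because the model is trained order-agnostically, the fully
    conditioned single-position distribution p(x_i | x_everything_else) is a
    trained quantity (the last-slot conditional); each sweep revisits every
    free slot in a fresh random order and redraws it given the complete
    current sequence context.  Fixed positions are never revisited and tied
    groups are redrawn jointly.
    """

    fixed: dict[int, str] = dataclasses.field(default_factory=dict)
    tied_groups: list[list[tuple[int, float]]] = dataclasses.field(default_factory=list)
    omit: set[str] = dataclasses.field(default_factory=lambda: {"X"})
    temperature: float = 0.1
    n_samples: int = 1
    seed: int = 0
    tie_mode: str = "logits"
    refine_sweeps: int = 0

    def __post_init__(self):
        self.omit = set(self.omit) | {"X"}
        if self.temperature <= 0:
            raise ConstraintError("temperature must be > 0")
        if self.tie_mode not in ("logits", "probs"):
            raise ConstraintError(f"unknown tie_mode {self.tie_mode!r}")
        if self.refine_sweeps < 0:
            raise ConstraintError("refine_sweeps must be >= 0")

    def validate(self, n_positions: int) -> None:
        tied_positions: set[int] = set()
        for group in self.tied_groups:
            if not group:
                raise ConstraintError("tied group must have at least one member")
            for pos, _coef in group:
                if not 0 <= pos < n_positions:
                    raise ConstraintError(f"tied position {pos} out of range")
                if pos in tied_positions:
                    raise ConstraintError(f"position {pos} appears in two tied groups")
                tied_positions.add(pos)
        for pos, letter in self.fixed.items():
            if not 0 <= pos < n_positions:
                raise ConstraintError(f"fixed position {pos} out of range")
            if letter.upper() not in AA_TO_INDEX:
                raise ConstraintError(f"unknown fixed letter {letter!r}")
            if letter.upper() in self.omit:
                raise ConstraintError(f"fixed letter {letter!r} is in the omit set")
        overlap = tied_positions & set(self.fixed)
        if overlap:
            raise ConstraintError(
                f"positions {sorted(overlap)} are both fixed and tied; "
                "mixed fixed/tied groups are rejected")


def parse_constraints(obj: dict, structure: BackboneStructure) -> DesignConstraints:
    """Build constraints from the JSON schema with 'A12'-style position keys."""
    fixed = {structure.position_of(k): v for k, v in obj.get("fixed", {}).items()}
    tied = [[(structure.position_of(p), float(c)) for p, c in group]
            for group in obj.get("tied", [])]
    return DesignConstraints(
        fixed=fixed,
        tied_groups=tied,
        omit=set(obj.get("omit", [])),
        temperature=float(obj.get("temperature", 0.1)),
        n_samples=int(obj.get("n_samples", 1)),
        seed=int(obj.get("seed", 0)),
        tie_mode=obj.get("tie_mode", "logits"),
    )


@dataclasses.dataclass
class DecodingOrder:
    """Ordered decoding slots; each slot is one position or one tied group."""

    slots: list[list[int]]
    coefficients: list[list[float]]
    n_fixed_slots: int = 0

    def ranks(self, n_positions: int) -> np.ndarray:
        r = np.full(n_positions, -1, dtype=np.int64)
        for rank, slot in enumerate(self.slots):
            for pos in slot:
                r[pos] = rank
        if (r < 0).any():
            raise ConstraintError("decoding order does not cover every position")
        return r


def sample_decoding_order(constraints: DesignConstraints, n_positions: int,
                          seed: int) -> DecodingOrder:
    """Uniformly random slot order subject to fixed-positions-first."""
    constraints.validate(n_positions)
    rng = np.random.default_rng(seed)
    fixed_slots = [[p] for p in sorted(constraints.fixed)]
    tied_positions = {p for g in constraints.tied_groups for p, _ in g}
    free_single = [[p] for p in range(n_positions)
                   if p not in constraints.fixed and p not in tied_positions]
    free_slots = [[p for p, _ in g] for g in constraints.tied_groups] + free_single
    free_coefs = [[c for _, c in g] for g in constraints.tied_groups] + \
                 [[1.0] for _ in free_single]
    fixed_perm = rng.permutation(len(fixed_slots))
    free_perm = rng.permutation(len(free_slots))
    slots = [fixed_slots[i] for i in fixed_perm] + [free_slots[i] for i in free_perm]
    coefs = [[1.0] for _ in fixed_perm] + [free_coefs[i] for i in free_perm]
    return DecodingOrder(slots=slots, coefficients=coefs, n_fixed_slots=len(fixed_slots))


def combine_tied_logits(logits_list: Sequence[np.ndarray],
                        coefficients: Sequence[float],
                        temperature: float,
                        omit: set[str],
                        mode: str = "logits") -> np.ndarray:
    """Single sampling distribution from tied-member (or multi-state) logits.

    "logits" mode: softmax(sum_i c_i * l_i / sum_i |c_i| / T) with omitted
    letters masked out beforehand.  "probs" mode: per-member softmax first,
    then the coefficient-weighted average, clipped and renormalised.
    """
    if len(logits_list) != len(coefficients) or not logits_list:
        raise ValueError("logits and coefficients must be equal-length, non-empty")
    coefs = np.asarray(coefficients, dtype=float)
    denom = np.abs(coefs).sum()
    if denom == 0:
        raise ValueError("all tied coefficients are zero")
    omit_idx = [AA_TO_INDEX[a] for a in omit if a in AA_TO_INDEX]
    if mode == "logits":
        combined = sum(c * np.asarray(l, dtype=float)
                       for c, l in zip(coefs, logits_list)) / denom
        combined[omit_idx] = -np.inf
        p = np.exp(nn.log_softmax(combined / temperature))
    else:
        acc = np.zeros_like(np.asarray(logits_list[0], dtype=float))
        for c, l in zip(coefs, logits_list):
            masked = np.asarray(l, dtype=float).copy()
            masked[omit_idx] = -np.inf
            acc += c * np.exp(nn.log_softmax(masked / temperature))
        p = np.clip(acc / denom, 0.0, None)
        if p.sum() <= 0:
            raise ValueError("averaged-probability combination is degenerate")
        p = p / p.sum()
    return p


@dataclasses.dataclass
class SampleResult:
    """One designed sequence with its sampling record."""

    tokens: np.ndarray
    chain_sequences: list[str]
    per_position_probs: np.ndarray  # (n, vocab) sampling distribution used
    per_position_log_probs: np.ndarray  # raw model log p(letter) per position
    avg_log_prob: float
    recovery: float | None
    order: DecodingOrder

    @property
    def sequence(self) -> str:
        return tokens_to_seq(self.tokens)


@dataclasses.dataclass
class DesignResult:
    """All samples for one design run."""

    samples: list[SampleResult]
    temperature: float
    seed: int
    constraints: DesignConstraints


class _EncodedState:
    """Encoder output cached for repeated decoding passes."""

    def __init__(self, params: ModelParams, config: ModelConfig,
                 structure: BackboneStructure):
        self.structure = structure
        self.batch = GraphBatch.from_graph(featurize(structure, config.featurizer))
        self.h_v, self.h_e = encode(self.batch, params, config, train=False)

    def logits(self, params, config, tokens: np.ndarray, attend: np.ndarray) -> np.ndarray:
        out = decode_logits(self.h_v, self.h_e, self.batch, tokens[None], attend[None],
                            params, config, train=False)
        return out.data[0]


def _decode_one(params, config, states: list[_EncodedState],
                state_coefs: np.ndarray, constraints: DesignConstraints,
                order: DecodingOrder, rng: np.random.Generator,
                greedy: bool = False):
    """Run one sampling pass over the slots of `order` across 1+ states."""
    n = states[0].structure.n_residues
    ranks = order.ranks(n)
    attends = [attend_from_ranks(ranks[None], st.batch.neighbor_index)[0]
               for st in states]
    tokens = np.zeros(n, dtype=np.int64)
    probs = np.zeros((n, config.vocab))
    logp = np.zeros(n)
    for slot, coefs in zip(order.slots, order.coefficients):
        per_state_logits = [st.logits(params, config, tokens, att)
                            for st, att in zip(states, attends)]
        # raw (unit-temperature, unmasked) log probabilities for scoring
        raw_lp = [nn.log_softmax(L[slot]) for L in per_state_logits]
        members_logits = [L[pos] for L in per_state_logits for pos in slot]
        members_coefs = [float(sc) * float(c)
                         for sc in state_coefs for c in coefs]
        first = slot[0]
        if first in constraints.fixed:
            letter = constraints.fixed[first].upper()
            tok = AA_TO_INDEX[letter]
            dist = combine_tied_logits(members_logits, members_coefs,
                                       constraints.temperature, constraints.omit,
                                       constraints.tie_mode)
        else:
            dist = combine_tied_logits(members_logits, members_coefs,
                                       constraints.temperature, constraints.omit,
                                       constraints.tie_mode)
            if greedy:
                tok = int(np.argmax(dist))
            else:
                tok = int(rng.choice(config.vocab, p=dist))
        for si, pos in enumerate(slot):
            tokens[pos] = tok
            probs[pos] = dist
            logp[pos] = raw_lp[0][si, tok]  # primary state's model log prob

    # optional conditional-resampling sweeps: each free slot is redrawn from
    # the fully conditioned distribution given the rest of the sequence
    free_slots = [(slot, coefs) for slot, coefs in zip(order.slots, order.coefficients)
                  if slot[0] not in constraints.fixed]
    for _sweep in range(constraints.refine_sweeps):
        for si in rng.permutation(len(free_slots)):
            slot, coefs = free_slots[si]
            ranks_last = np.zeros(n, dtype=np.int64)
            ranks_last[slot] = 1  # slot members see everyone else as context
            attends_last = [attend_from_ranks(ranks_last[None], st.batch.neighbor_index)[0]
                            for st in states]
            per_state_logits = [st.logits(params, config, tokens, att)
                                for st, att in zip(states, attends_last)]
            raw_lp = [nn.log_softmax(L[slot]) for L in per_state_logits]
            members_logits = [L[pos] for L in per_state_logits for pos in slot]
            members_coefs = [float(sc) * float(c) for sc in state_coefs for c in coefs]
            dist = combine_tied_logits(members_logits, members_coefs,
                                       constraints.temperature, constraints.omit,
                                       constraints.tie_mode)
            tok = int(np.argmax(dist)) if greedy else int(rng.choice(config.vocab, p=dist))
            for mi, pos in enumerate(slot):
                tokens[pos] = tok
                probs[pos] = dist
                logp[pos] = raw_lp[0][mi, tok]
    return tokens, probs, logp


def sample_sequence(params: ModelParams, config: ModelConfig,
                    structure: BackboneStructure,
                    constraints: DesignConstraints,
                    reference: str | None = None,
                    orders: Sequence[DecodingOrder] | None = None,
                    greedy: bool = False) -> DesignResult:
    """Sample `constraints.n_samples` sequences for one backbone.

    The encoder runs once; each sample draws its own decoding order (unless
    `orders` pins them) and its own letters, all derived from
    `constraints.seed`.  When `reference` is given, per-sample recovery
    against it is reported.
    """
    constraints.validate(structure.n_residues)
    state = _EncodedState(params, config, structure)
    return _run_sampling(params, config, [state], np.array([1.0]), constraints,
                         reference, orders, greedy)


def sample_multistate(params: ModelParams, config: ModelConfig,
                      structures: Sequence[BackboneStructure],
                      state_coefficients: Sequence[float],
                      constraints: DesignConstraints,
                      reference: str | None = None,
                      orders: Sequence[DecodingOrder] | None = None,
                      greedy: bool = False) -> DesignResult:
    """Design one sequence against several backbone states at once.

    States are featurised and encoded independently; at every slot the
    per-state logits are combined with the signed `state_coefficients`
    (positive favours, negative disfavours a state).  Positions are matched
    by index, so all states must have equal length.
    """
    lengths = {s.n_residues for s in structures}
    if len(lengths) != 1:
        raise ConstraintError("multi-state design requires equal-length states")
    if len(structures) != len(state_coefficients):
        raise ConstraintError("one coefficient per state is required")
    constraints.validate(structures[0].n_residues)
    states = [_EncodedState(params, config, s) for s in structures]
    return _run_sampling(params, config, states,
                         np.asarray(state_coefficients, dtype=float),
                         constraints, reference, orders, greedy)


def _run_sampling(params, config, states, state_coefs, constraints,
                  reference, orders, greedy) -> DesignResult:
    from .scoring import sequence_recovery  # local import to avoid a cycle

    n = states[0].structure.n_residues
    samples: list[SampleResult] = []
    for s_idx in range(constraints.n_samples):
        if orders is not None:
            order = orders[s_idx]
        else:
            order = sample_decoding_order(
                constraints, n, substream_seed(constraints.seed, "order", s_idx))
        rng = substream(constraints.seed, "draw", s_idx)
        tokens, probs, logp = _decode_one(params, config, states, state_coefs,
                                          constraints, order, rng, greedy)
        seq = tokens_to_seq(tokens)
        chain_seqs = [seq[sl] for sl in states[0].structure.chain_sequence_slices()]
        rec = None if reference is None else sequence_recovery(seq, reference)
        samples.append(SampleResult(
            tokens=tokens, chain_sequences=chain_seqs,
            per_position_probs=probs, per_position_log_probs=logp,
            avg_log_prob=float(logp.mean()), recovery=rec, order=order))
    return DesignResult(samples=samples, temperature=constraints.temperature,
                        seed=constraints.seed, constraints=constraints)


def tying_from_symmetry(structure: BackboneStructure, mode: str,
                        repeat_length: int | None = None) -> list[list[tuple[int, float]]]:
    """Tied groups for cyclic (between-chain) and repeat (within-chain) symmetry.

    "tie_chains" groups position i across all chains (equal chain lengths
    required).  "tie_repeats" additionally groups i with i + repeat_length,
    i + 2*repeat_length, ... within each chain.  Coefficients are all 1.
    """
    if mode == "none":
        return []
    lengths = structure.chain_lengths()
    slices = structure.chain_sequence_slices()
    if mode == "tie_chains":
        if len(set(lengths)) != 1:
            raise ConstraintError("tie_chains requires equal-length chains")
        return [[(sl.start + i, 1.0) for sl in slices] for i in range(lengths[0])]
    if mode == "tie_repeats":
        if repeat_length is None or repeat_length < 1:
            raise ConstraintError("tie_repeats requires a positive repeat_length")
        if len(set(lengths)) != 1:
            raise ConstraintError("tie_repeats requires equal-length chains")
        L = lengths[0]
        if L % repeat_length:
            raise ConstraintError(
                f"chain length {L} not divisible by repeat_length {repeat_length}")
        groups = []
        for i in range(repeat_length):
            group = [(sl.start + j * repeat_length + i, 1.0)
                     for sl in slices for j in range(L // repeat_length)]
            groups.append(group)
        return groups
    raise ConstraintError(f"unknown tying mode {mode!r}")
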