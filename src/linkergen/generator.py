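"""Linker generation: corpus augmentation, reward shaping, and Monte Carlo
tree search over SMILES token prefixes.

The search couples the recurrent policy (:class:`~linkergen.policy.SmilesPolicy`)
with a reward that favours permeable PROTACs: a candidate linker is assembled
with the POI and E3 ligands, the permeability model predicts the PROTAC's
log10 P_app, and the reward is a left-sided Gaussian of that prediction —
1 for predictions at or above μ, decaying as exp(−(x−μ)²/2σ²) below it.
Candidates failing the filter cascade receive a fixed penalty reward
(default 0) and still consume budget, so the tree learns to avoid dead
regions of token space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import mol_from_smiles
from .errors import ConfigError
from .filters import FilterConfig, FilterReferences, FilterReport, apply_preset
from .permeability import PermeabilityRegressor
from .policy import SmilesPolicy

# ---------------------------------------------------------------------------
# corpus augmentation
# ---------------------------------------------------------------------------


def augment_corpus(
    linkers: list[str], n_randomizations: int = 4, seed: int = 0
) -> list[str]:
    """Add random SMILES rewritings of each linker to the corpus.

    Each input contributes its original spelling plus up to
    ``n_randomizations`` randomized spellings of the same molecule;
    exact-string duplicates are removed while preserving first-seen order.
    """
    out: list[str] = []
    seen: set[str] = set()
    for i, smi in enumerate(linkers):
        variants = [smi]
        if n_randomizations > 0:
            mol = mol_from_smiles(smi, lenient=True)
            variants += list(
                Chem.MolToRandomSmilesVect(mol, n_randomizations, randomSeed=seed + i)
            )
        for v in variants:
            if v not in seen:
                seen.add(v)
                out.append(v)
    return out


def train_policy(
    corpus: list[str], epochs: int = 15, seed: int = 0, **policy_params
) -> SmilesPolicy:
    """Train the recurrent next-token policy on a (pre-augmented) corpus."""
    return SmilesPolicy(epochs=epochs, random_state=seed, **policy_params).fit(corpus)


# ---------------------------------------------------------------------------
# reward
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RewardConfig:
    """Left-sided Gaussian reward on predicted log10 P_app (μcm/s scale).

    Predictions at or above ``mu`` saturate at reward 1; below it the reward
    decays as a Gaussian with width ``sigma``. Filter-failing candidates get
    ``filtered_reward``.
    """

    mu: float = 0.25
    sigma: float = 1.0
    filtered_reward: float = 0.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def permeability_reward(x: float, cfg: RewardConfig = RewardConfig()) -> float:
    """Reward of a predicted log10 P_app: 1 above μ, Gaussian tail below."""
    if not math.isfinite(x):
        raise ValueError(f"prediction must be finite, got {x}")
    if x >= cfg.mu:
        return 1.0
    return math.exp(-((x - cfg.mu) ** 2) / (2.0 * cfg.sigma**2))


# ---------------------------------------------------------------------------
# candidate evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationContext:
    """Everything needed to score one candidate linker."""

    model: PermeabilityRegressor
    preset: str
    filter_config: FilterConfig
    references: FilterReferences
    reward: RewardConfig = field(default_factory=RewardConfig)
    skip_alert: bool = False


def evaluate_candidate(
    smiles: str, ctx: EvaluationContext
) -> tuple[FilterReport, float, float]:
    """Filter, assemble, predict and score one candidate linker.

    Returns (filter report, reward, predicted mean log10 P_app). The
    prediction is NaN when the cascade rejects the candidate before assembly
    or prediction.
    """
    report = apply_preset(
        smiles, ctx.preset, ctx.filter_config, ctx.references, skip_alert=ctx.skip_alert
    )
    if not report.passed:
        return report, ctx.reward.filtered_reward, float("nan")
    mean = float(ctx.model.predict([report.protac_smiles])[0])
    return report, permeability_reward(mean, ctx.reward), mean


# ---------------------------------------------------------------------------
# search tree
# ---------------------------------------------------------------------------


@dataclass
class SearchNode:
    """One token prefix in the search tree."""

    token_id: int
    prefix: list[int]                 # token ids including the begin symbol
    h: np.ndarray                     # policy hidden state after the prefix
    probs: np.ndarray                 # next-token distribution after the prefix
    terminal: bool = False
    visits: int = 0
    value_sum: float = 0.0
    expanded: bool = False
    children: list["SearchNode"] = field(default_factory=list)

    @property
    def mean_value(self) -> float:
        return self.value_sum / self.visits if self.visits else 0.0


def ucb_select(
    children: list[SearchNode], parent_visits: int, ucb_c: float
) -> SearchNode:
    """UCB1 child selection.

    Unvisited children rank above all visited ones (earliest index first);
    among visited children the score is mean reward +
    ucb_c·sqrt(2·ln(parent_visits)/visits), ties broken by lowest index.
    """
    if not children:
        raise ValueError("cannot select from an empty child list")
    for child in children:
        if child.visits == 0:
            return child
    log_n = math.log(max(parent_visits, 1))
    best, best_score = children[0], -math.inf
    for child in children:
        score = child.mean_value + ucb_c * math.sqrt(2.0 * log_n / child.visits)
        if score > best_score + 1e-15:
            best, best_score = child, score
    return best


@dataclass
class GenerationEntry:
    index: int
    smiles: str
    passed: bool
    failed_at: str | None
    predicted_mean: float
    reward: float


@dataclass
class GenerationLog:
    """Time-ordered record of one search run."""

    entries: list[GenerationEntry]
    seed: int
    preset: str
    budget: int

    def rewards(self) -> np.ndarray:
        return np.array([e.reward for e in self.entries])

    def running_max(self) -> np.ndarray:
        return np.maximum.accumulate(self.rewards()) if self.entries else np.array([])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [e.index for e in self.entries],
                "smiles": [e.smiles for e in self.entries],
                "passed": [e.passed for e in self.entries],
                "failed_at": [e.failed_at or "" for e in self.entries],
                "predicted_mean": [e.predicted_mean for e in self.entries],
                "reward": [e.reward for e in self.entries],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def mcts_search(
    policy: SmilesPolicy,
    evaluator,
    budget: int,
    seed: int = 0,
    ucb_c: float = 1.0,
    expansion_k: int = 10,
    min_expand_prob: float = 0.02,
    preset: str = "unknown",
    count_valid_only: bool = False,
    max_iterations: int | None = None,
) -> GenerationLog:
    """Monte Carlo tree search over SMILES token prefixes.

    Each iteration selects a path by UCB1, expands a leaf with the policy's
    top-``expansion_k`` next tokens (dropping tokens below
    ``min_expand_prob`` policy probability — without this pruning UCB1's
    visit-each-child-once rule wastes most of the budget on token
    continuations the language model considers ungrammatical), completes the
    prefix by temperature-1 policy sampling (the rollout), scores the
    resulting string with ``evaluator(smiles) -> reward``, and backs the
    reward up along the path.
    Rewards of previously seen strings come from a cache; the string is still
    logged and still updates the tree.

    ``budget`` counts generated strings. With ``count_valid_only=True`` only
    strings passing their filter report count toward the budget (the
    evaluator must then return ``(reward, passed)`` via the wrapper used in
    the workbench); the default counts every attempt.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not hasattr(policy, "vocab_"):
        raise ConfigError("policy must be fitted before search")
    rng = np.random.default_rng(seed)
    vocab = policy.vocab_

    h0, p0 = policy.run_prefix([0])
    root = SearchNode(token_id=0, prefix=[0], h=h0, probs=p0)

    cache: dict[str, tuple[float, bool, str | None, float]] = {}
    entries: list[GenerationEntry] = []
    counted = 0
    iterations = 0
    iter_cap = max_iterations if max_iterations is not None else (
        budget if not count_valid_only else 100 * budget
    )

    def expand(node: SearchNode) -> None:
        top = np.argsort(-node.probs, kind="stable")[:expansion_k]
        for tid in top:
            tid = int(tid)
            if tid == 0 or node.probs[tid] < min_expand_prob:
                continue  # never re-emit the begin symbol; prune junk tokens
            h2, p2 = policy.step(node.h, tid)
            node.children.append(
                SearchNode(
                    token_id=tid,
                    prefix=node.prefix + [tid],
                    h=h2,
                    probs=p2,
                    terminal=(tid == 1),
                )
            )
        node.expanded = True

    def rollout(node: SearchNode) -> str:
        if node.terminal:
            return vocab.decode([t for t in node.prefix[1:] if t != 1])
        ids = [t for t in node.prefix[1:] if t != 1]
        h, probs = node.h, node.probs
        while len(ids) < policy.max_len:
            tid = int(rng.choice(len(probs), p=probs))
            if tid == 1:
                break
            ids.append(tid)
            h, probs = policy.step(h, tid)
        return vocab.decode(ids)

    while counted < budget and iterations < iter_cap:
        iterations += 1
        node, path = root, [root]
        while node.expanded and node.children and not node.terminal:
            node = ucb_select(node.children, node.visits, ucb_c)
            path.append(node)
        if not node.terminal and not node.expanded:
            expand(node)
            if node.children:
                node2 = ucb_select(node.children, max(node.visits, 1), ucb_c)
                path.append(node2)
                node = node2

        smiles = rollout(node)
        if smiles in cache:
            reward, passed, failed_at, pred = cache[smiles]
        else:
            result = evaluator(smiles)
            if isinstance(result, tuple) and len(result) == 3:
                report, reward, pred = result
                passed, failed_at = report.passed, report.failed_at()
            else:
                reward, passed, failed_at, pred = float(result), True, None, float("nan")
            cache[smiles] = (reward, passed, failed_at, pred)

        for n in path:
            n.visits += 1
            n.value_sum += reward

        if count_valid_only and not passed:
            continue
        entries.append(
            GenerationEntry(
                index=counted,
                smiles=smiles,
                passed=passed,
                failed_at=failed_at,
                predicted_mean=pred,
                reward=reward,
            )
        )
        counted += 1

    log = GenerationLog(entries=entries, seed=seed, preset=preset, budget=budget)
    log.root_ = root  # search tree, exposed for inspection/debugging
    return log
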