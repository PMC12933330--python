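"""SMILES tokenizer and recurrent next-token policy.

The policy is a character-level (token-level) language model over linker
SMILES: an embedding layer feeding a single tanh recurrent layer with a
softmax read-out, trained by full-sequence backpropagation with Adam. It is
implemented directly in NumPy, which keeps fits deterministic for a fixed
seed and fast at the corpus sizes this package targets (thousands of short
strings).

Tokenization treats multi-character atoms ("Cl", "Br", bracket atoms like
"[nH]" or "[C@@H]") and two-digit ring closures ("%12") as single tokens, so
detokenize(tokenize(s)) == s for every valid SMILES. The attachment marker
"*" is an ordinary token.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, TokenError

BOS = "^"
EOS = "$"

_TOKEN_RE = re.compile(
    r"\[[^\]]+\]"      # bracket atom (one token)
    r"|Br|Cl"          # two-letter organic-subset elements
    r"|%\d{2}"         # two-digit ring closure
    r"|[BCNOPSFIbcnops0-9*=#()+\-/\\.:~]"
)


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into tokens; unknown symbols raise TokenError."""
    tokens = []
    pos = 0
    while pos < len(smiles):
        m = _TOKEN_RE.match(smiles, pos)
        if m is None:
            raise TokenError(f"unknown symbol {smiles[pos]!r} at position {pos} in {smiles!r}")
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


def detokenize(tokens: list[str]) -> str:
    return "".join(tokens)


@dataclass
class TokenVocabulary:
    """Ordered token set with begin/end symbols at fixed indices 0/1."""

    tokens: list[str]

    def __post_init__(self):
        if self.tokens[:2] != [BOS, EOS]:
            raise ConfigError("vocabulary must start with the begin and end symbols")
        self.index = {t: i for i, t in enumerate(self.tokens)}
        if len(self.index) != len(self.tokens):
            raise ConfigError("duplicate tokens in vocabulary")

    def __len__(self) -> int:
        return len(self.tokens)

    @classmethod
    def from_corpus(cls, corpus: list[str]) -> "TokenVocabulary":
        seen: set[str] = set()
        for s in corpus:
            seen.update(tokenize(s))
        return cls([BOS, EOS] + sorted(seen))

    def encode(self, smiles: str) -> list[int]:
        try:
            return [self.index[t] for t in tokenize(smiles)]
        except KeyError as exc:
            raise TokenError(f"token {exc.args[0]!r} not in vocabulary") from exc

    def decode(self, ids: list[int]) -> str:
        return detokenize([self.tokens[i] for i in ids])


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class SmilesPolicy:
    """Recurrent next-token policy over SMILES linkers.

    Parameters
    ----------
    hidden_size, embed_size : network widths.
    epochs, batch_size, lr : training schedule (Adam, gradient-norm clip 5).
    max_len : hard cap on sampled sequence length, in tokens.
    random_state : seeds weight initialization, batch shuffling and sampling.

    Fitted attributes: ``vocab_`` (the token vocabulary), ``losses_`` (mean
    next-token negative log-likelihood per epoch), and the weight matrices.
    """

    def __init__(
        self,
        hidden_size: int = 64,
        embed_size: int = 32,
        epochs: int = 15,
        batch_size: int = 32,
        lr: float = 5e-3,
        max_len: int = 80,
        random_state: int = 0,
    ):
        self.hidden_size = hidden_size
        self.embed_size = embed_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.max_len = max_len
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, corpus: list[str]) -> "SmilesPolicy":
        """Train the next-token model on a corpus of SMILES strings."""
        if not corpus:
            raise ConfigError("training corpus is empty")
        self.vocab_ = TokenVocabulary.from_corpus(corpus)
        rng = np.random.default_rng(self.random_state)
        V, D, H = len(self.vocab_), self.embed_size, self.hidden_size
        scale = 0.1
        self.E_ = rng.normal(0, scale, (V, D))
        self.Wx_ = rng.normal(0, scale, (D, H))
        self.Wh_ = rng.normal(0, scale, (H, H))
        self.bh_ = np.zeros(H)
        self.Wo_ = rng.normal(0, scale, (H, V))
        self.bo_ = np.zeros(V)

        seqs = [[0] + self.vocab_.encode(s) + [1] for s in corpus]
        params = [self.E_, self.Wx_, self.Wh_, self.bh_, self.Wo_, self.bo_]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        self.losses_ = []
        order = np.arange(len(seqs))
        for _epoch in range(self.epochs):
            rng.shuffle(order)
            tot_nll, tot_tok = 0.0, 0
            for start in range(0, len(seqs), self.batch_size):
                batch = [seqs[i] for i in order[start : start + self.batch_size]]
                nll, ntok, grads = self._batch_grads(batch)
                tot_nll += nll
                tot_tok += ntok
                # global-norm gradient clip
                norm = np.sqrt(sum(float((g * g).sum()) for g in grads))
                if norm > 5.0:
                    grads = [g * (5.0 / norm) for g in grads]
                step += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    mhat = mi / (1 - beta1**step)
                    vhat = vi / (1 - beta2**step)
                    p -= self.lr * mhat / (np.sqrt(vhat) + eps)
            self.losses_.append(tot_nll / tot_tok)
        self._rng = np.random.default_rng(self.random_state + 1)
        return self

    def _batch_grads(self, batch: list[list[int]]):
        B = len(batch)
        T = max(len(s) for s in batch) - 1
        V, D, H = self.E_.shape[0], self.embed_size, self.hidden_size
        inp = np.zeros((B, T), dtype=np.int64)
        tgt = np.zeros((B, T), dtype=np.int64)
        mask = np.zeros((B, T))
        for b, s in enumerate(batch):
            L = len(s) - 1
            inp[b, :L] = s[:-1]
            tgt[b, :L] = s[1:]
            mask[b, :L] = 1.0

        hs = np.zeros((T + 1, B, H))
        probs = np.zeros((T, B, V))
        for t in range(T):
            x = self.E_[inp[:, t]]
            hs[t + 1] = np.tanh(x @ self.Wx_ + hs[t] @ self.Wh_ + self.bh_)
            probs[t] = _softmax(hs[t + 1] @ self.Wo_ + self.bo_)

        ntok = mask.sum()
        rows = np.arange(B)
        nll = 0.0
        for t in range(T):
            p = probs[t][rows, tgt[:, t]]
            nll -= float((np.log(np.maximum(p, 1e-12)) * mask[:, t]).sum())

        dE = np.zeros_like(self.E_)
        dWx = np.zeros_like(self.Wx_)
        dWh = np.zeros_like(self.Wh_)
        dbh = np.zeros_like(self.bh_)
        dWo = np.zeros_like(self.Wo_)
        dbo = np.zeros_like(self.bo_)
        dh_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            dlog = probs[t].copy()
            dlog[rows, tgt[:, t]] -= 1.0
            dlog *= (mask[:, t] / ntok)[:, None]
            dWo += hs[t + 1].T @ dlog
            dbo += dlog.sum(axis=0)
            dh = dlog @ self.Wo_.T + dh_next
            dpre = dh * (1.0 - hs[t + 1] ** 2)
            x = self.E_[inp[:, t]]
            dWx += x.T @ dpre
            dWh += hs[t].T @ dpre
            dbh += dpre.sum(axis=0)
            np.add.at(dE, inp[:, t], dpre @ self.Wx_.T)
            dh_next = dpre @ self.Wh_.T
        return nll, ntok, [dE, dWx, dWh, dbh, dWo, dbo]

    # ------------------------------------------------------------------
    # stepping interface (used by sampling and by tree search)
    # ------------------------------------------------------------------
    def init_state(self) -> np.ndarray:
        self._check_fitted()
        return np.zeros(self.hidden_size)

    def step(self, h: np.ndarray, token_id: int) -> tuple[np.ndarray, np.ndarray]:
        """Advance the hidden state by one token; return (h', next-token probs)."""
        x = self.E_[token_id]
        h2 = np.tanh(x @ self.Wx_ + h @ self.Wh_ + self.bh_)
        return h2, _softmax(h2 @ self.Wo_ + self.bo_)

    def run_prefix(self, token_ids: list[int]) -> tuple[np.ndarray, np.ndarray]:
        """Hidden state and next-token probabilities after consuming a prefix
        (the prefix should start with the begin symbol, id 0)."""
        h = self.init_state()
        probs = None
        for tid in token_ids:
            h, probs = self.step(h, tid)
        if probs is None:
            _, probs = self.step(self.init_state(), 0)
        return h, probs

    def next_token_probs(self, token_ids: list[int]) -> np.ndarray:
        return self.run_prefix(token_ids)[1]

    def sample(
        self,
        rng: np.random.Generator | None = None,
        prefix_ids: list[int] | None = None,
        temperature: float = 1.0,
    ) -> str:
        """Sample a complete SMILES string (temperature-1 by default).

        Sampling starts after the begin symbol (or after ``prefix_ids``) and
        stops at the end symbol or at ``max_len`` tokens.
        """
        self._check_fitted()
        rng = rng if rng is not None else self._rng
        ids = list(prefix_ids) if prefix_ids else [0]
        h, probs = self.run_prefix(ids)
        out = [i for i in ids[1:] if i != 1]
        while len(out) < self.max_len:
            p = probs
            if temperature != 1.0:
                logp = np.log(np.maximum(p, 1e-12)) / temperature
                p = _softmax(logp)
            tid = int(rng.choice(len(p), p=p))
            if tid == 1:  # end symbol
                break
            out.append(tid)
            h, probs = self.step(h, tid)
        return self.vocab_.decode(out)

    def sequence_probability(self, smiles: str) -> float:
        """Probability the policy assigns to generating exactly this string."""
        self._check_fitted()
        ids = [0] + self.vocab_.encode(smiles) + [1]
        h = self.init_state()
        logp = 0.0
        for cur, nxt in zip(ids[:-1], ids[1:]):
            h, probs = self.step(h, cur)
            logp += float(np.log(np.maximum(probs[nxt], 1e-300)))
        return float(np.exp(logp))

    def top_k_tokens(self, token_ids: list[int], k: int) -> list[int]:
        """The k most probable next tokens after a prefix, most probable first."""
        probs = self.next_token_probs(token_ids)
        order = np.argsort(-probs, kind="stable")
        return [int(i) for i in order[:k]]

    def _check_fitted(self):
        if not hasattr(self, "E_"):
            raise ConfigError("policy is not fitted")
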