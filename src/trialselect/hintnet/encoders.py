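"""Input encoders for the three trial components.

* drugs: hashed circular-substructure (Morgan) fingerprints through a learned
  perceptron; the trial-level drug embedding is the mean over molecules.
* diseases: attention over each code's ontology ancestors (GRAM-style), so
  rare codes borrow statistical strength from their parents; the trial-level
  disease embedding is the mean over codes.
* protocol: hashed bag-of-token sentence vectors through a stack of four
  one-dimensional convolutions with kernel sizes 2, 3, 4, 5 capturing four
  granularities of criteria phrasing, mean-pooled and projected to d.
"""

from __future__ import annotations

import hashlib
import warnings

import numpy as np

from .._autodiff import Tensor, concat
from .layers import Module, Linear, MLP
from .records import Ontology

__all__ = ["MoleculeEncoder", "DiseaseEncoder", "ProtocolEncoder",
           "hashed_sentence_vector", "morgan_fingerprint"]

_FP_BITS = 1024
_FP_RADIUS = 2


def morgan_fingerprint(smiles: str) -> np.ndarray:
    """Radius-2, 1024-bit circular fingerprint of one molecule."""
    from rdkit import Chem, RDLogger
    from rdkit.Chem import AllChem

    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    bv = AllChem.GetMorganFingerprintAsBitVect(mol, _FP_RADIUS, nBits=_FP_BITS)
    arr = np.zeros(_FP_BITS, dtype=np.float64)
    for bit in bv.GetOnBits():
        arr[bit] = 1.0
    return arr


def _stable_hash(token: str, salt: str = "") -> int:
    digest = hashlib.md5((salt + token).encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


def hashed_sentence_vector(sentence: str, d: int) -> np.ndarray:
    """Deterministic hashed bag-of-token embedding of one criterion sentence."""
    vec = np.zeros(d, dtype=np.float64)
    tokens = sentence.lower().split()
    for tok in tokens:
        h = _stable_hash(tok)
        idx = h % d
        sign = 1.0 if (h >> 32) & 1 else -1.0
        vec[idx] += sign
    if tokens:
        vec /= np.sqrt(len(tokens))
    return vec


class MoleculeEncoder(Module):
    """Fingerprint -> d perceptron; trial embedding is the molecule mean."""

    def __init__(self, d: int, rng: np.random.Generator):
        self.proj = Linear(_FP_BITS, d, rng)
        self.d = d
        self._fp_cache: dict[str, np.ndarray] = {}

    def featurize(self, drug_lists: list[list[str]]) -> np.ndarray:
        """Mean fingerprint per trial, shape (n_trials, 1024)."""
        out = np.zeros((len(drug_lists), _FP_BITS))
        for i, drugs in enumerate(drug_lists):
            if not drugs:
                raise ValueError("trial with empty drug list")
            fps = []
            for smi in drugs:
                if smi not in self._fp_cache:
                    self._fp_cache[smi] = morgan_fingerprint(smi)
                fps.append(self._fp_cache[smi])
            out[i] = np.mean(fps, axis=0)
        return out

    def __call__(self, mean_fps: np.ndarray) -> Tensor:
        # linear projection: the mean over molecule embeddings then equals
        # the embedding of the mean fingerprint exactly
        return self.proj(Tensor(mean_fps))

    def encode(self, drug_lists: list[list[str]]) -> Tensor:
        return self(self.featurize(drug_lists))


class DiseaseEncoder(Module):
    """Ancestor-attention embedding over a disease ontology.

    Each code owns a learnable basis vector; a two-layer scorer rates each
    (code, ancestor) pair and a softmax over the ancestor set yields the
    attention mixture.  A code with no ancestors besides itself reduces to
    its own basis vector.
    """

    def __init__(self, d: int, ontology: Ontology, rng: np.random.Generator):
        self.d = d
        self.ontology = ontology
        self.vocab = sorted(ontology.codes)
        self._code_index = {c: i for i, c in enumerate(self.vocab)}
        n = len(self.vocab)
        self.basis = Tensor(rng.normal(0.0, 0.3, size=(n, d)), requires_grad=True)
        self.scorer = MLP([2 * d, d, 1], rng)
        # flattened (code, ancestor) pair indices and the segment mask used
        # to normalize attention per code
        code_idx, anc_idx = [], []
        for c in self.vocab:
            ci = self._code_index[c]
            for a in ontology.ancestors(c):
                code_idx.append(ci)
                anc_idx.append(self._code_index[a])
        self._code_idx = np.asarray(code_idx)
        self._anc_idx = np.asarray(anc_idx)
        seg = np.zeros((n, len(code_idx)))
        seg[self._code_idx, np.arange(len(code_idx))] = 1.0
        self._seg = seg  # (n_codes, n_pairs)

    def code_embeddings(self) -> Tensor:
        """Embedding matrix for the whole vocabulary, shape (n_codes, d)."""
        pair_in = concat([self.basis[self._code_idx], self.basis[self._anc_idx]],
                         axis=1)
        scores = self.scorer(pair_in)                      # (n_pairs, 1)
        shifted = scores - float(scores.data.max())        # shared shift, per-segment softmax unchanged
        e = shifted.exp()                                  # (n_pairs, 1)
        seg = Tensor(self._seg)
        denom = seg @ e                                    # (n_codes, 1)
        weights = e / (denom[self._code_idx])              # (n_pairs, 1)
        weighted = weights * self.basis[self._anc_idx]     # (n_pairs, d)
        return seg @ weighted                              # (n_codes, d)

    def attention_weights(self, code: str) -> dict[str, float]:
        """Normalized ancestor attention for one code (diagnostic view)."""
        pair_in = concat([self.basis[self._code_idx], self.basis[self._anc_idx]],
                         axis=1)
        scores = self.scorer(pair_in).data.ravel()
        ci = self._code_index[code]
        mask = self._code_idx == ci
        s = scores[mask]
        w = np.exp(s - s.max())
        w /= w.sum()
        return {self.vocab[a]: float(x)
                for a, x in zip(self._anc_idx[mask], w)}

    def trial_matrix(self, disease_lists: list[list[str]]) -> np.ndarray:
        """Averaging matrix M with M @ code_embeddings = trial embeddings."""
        m = np.zeros((len(disease_lists), len(self.vocab)))
        for i, codes in enumerate(disease_lists):
            if not codes:
                raise ValueError("trial with empty disease list")
            for c in codes:
                if c not in self._code_index:
                    raise KeyError(f"unknown ontology code {c!r}")
                m[i, self._code_index[c]] += 1.0 / len(codes)
        return m

    def encode(self, disease_lists: list[list[str]]) -> Tensor:
        return Tensor(self.trial_matrix(disease_lists)) @ self.code_embeddings()


class ProtocolEncoder(Module):
    """Criteria sentences -> d via a 4-layer 1-D convolution stack.

    Sentence vectors come from a pluggable encoder (default: hashed
    bag-of-tokens); a heavier contextual sentence encoder can be swapped in
    through ``sentence_fn``.  Convolutions use zero same-padding so short
    protocols (down to one criterion) remain valid; pooling is a masked mean
    over the true sentence positions.  The stack is order-sensitive by
    construction: criteria are consumed in their listed order.
    """

    KERNELS = (2, 3, 4, 5)

    def __init__(self, d: int, rng: np.random.Generator, sentence_fn=None):
        self.d = d
        self.sentence_fn = sentence_fn or (lambda s: hashed_sentence_vector(s, d))
        # per conv layer: weight (k, d, d) stored as k separate (d, d) mats
        self.conv_weights = []
        self.conv_biases = []
        for k in self.KERNELS:
            ws = [Tensor(rng.normal(0, np.sqrt(2.0 / (k * d)), size=(d, d)),
                         requires_grad=True)
                  for _ in range(k)]
            self.conv_weights.append(ws)
            self.conv_biases.append(Tensor(np.zeros(d), requires_grad=True))
        self.out = Linear(d, d, rng)

    def parameters(self):
        params = []
        for ws in self.conv_weights:
            params.extend(ws)
        params.extend(self.conv_biases)
        params.extend(self.out.parameters())
        return params

    def featurize(self, protocols: list[list[tuple[str, str]]]):
        """Stack per-trial sentence matrices into (n, L, d) plus a mask."""
        lengths = [max(1, len(p)) for p in protocols]
        L = max(lengths)
        x = np.zeros((len(protocols), L, self.d))
        mask = np.zeros((len(protocols), L))
        for i, proto in enumerate(protocols):
            if not proto:
                warnings.warn("trial with empty protocol: protocol embedding "
                              "falls back to the zero vector", stacklevel=2)
                mask[i, 0] = 1.0
                continue
            for j, (tag, sentence) in enumerate(proto):
                # inclusion/exclusion polarity enters as a leading token
                prefix = "inclusion" if tag == "+" else "exclusion"
                x[i, j] = np.asarray(
                    self.sentence_fn(f"{prefix} {sentence}"), dtype=float)
                mask[i, j] = 1.0
        return x, mask

    def _conv(self, x: Tensor, ws: list[Tensor], b: Tensor) -> Tensor:
        k = len(ws)
        n, L, d = x.shape
        left = (k - 1) // 2
        right = k - 1 - left
        pad_l = Tensor(np.zeros((n, left, d)))
        pad_r = Tensor(np.zeros((n, right, d)))
        xp = concat([pad_l, x, pad_r], axis=1)
        out = None
        for j in range(k):
            term = xp[:, j:j + L, :] @ ws[j]
            out = term if out is None else out + term
        return out + b

    def __call__(self, x: np.ndarray, mask: np.ndarray) -> Tensor:
        h = Tensor(x)
        for i in range(len(self.KERNELS)):
            h = self._conv(h, self.conv_weights[i], self.conv_biases[i])
            if i < len(self.KERNELS) - 1:
                h = h.relu()
        m = Tensor(mask[:, :, None])
        pooled = (h * m).sum(axis=1) / Tensor(mask.sum(axis=1)[:, None])
        return self.out(pooled)

    def encode(self, protocols: list[list[tuple[str, str]]]) -> Tensor:
        x, mask = self.featurize(protocols)
        return self(x, mask)
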