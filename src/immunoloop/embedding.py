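"""Fixed low-dimensional latent representations of the candidate library.

Two providers with one downstream contract (a ``LatentSpace``):

* ``train_vae`` / ``VaeEmbedder`` — a variational autoencoder over one-hot
  SELFIES token sequences: fully-connected encoder (default desk-scale
  64-32-16, ``paper`` preset 500-200-100 with a 100D latent), Gaussian
  latent with reparameterization, and a 2-layer GRU decoder trained with
  teacher forcing.  Implemented in NumPy with hand-written backprop and
  Adam, deterministic given the seed.
* ``fingerprint_embedding`` — ECFP4 bit vectors cast to reals; drop-in
  replacement for the VAE coordinates downstream.

Per-molecule coordinates are always the posterior mean, so the embedding is
deterministic and frozen between active-learning rounds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np

from immunoloop import chemlib
from immunoloop.chemlib import CandidateLibrary, Molecule, TokenVocabulary

logger = logging.getLogger(__name__)


@dataclass
class VaeConfig:
    encoder_widths: tuple[int, ...] = (64, 32, 16)
    latent_dim: int = 16
    gru_layers: int = 2
    gru_hidden: int = 64
    embed_dim: int = 16
    kl_weight: float = 1.0          # beta
    kl_warmup_frac: float = 0.1     # linear beta ramp over first 10% of epochs
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be >= 0")

    @classmethod
    def paper_preset(cls, **overrides) -> "VaeConfig":
        """The full-scale architecture (500-200-100 encoder, 100D latent,
        2 GRU layers); not trained in the test suite."""
        kw = dict(encoder_widths=(500, 200, 100), latent_dim=100,
                  gru_layers=2, gru_hidden=256, embed_dim=64)
        kw.update(overrides)
        return cls(**kw)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class LatentSpace:
    """One fixed coordinate vector per molecule id."""

    ids: list[str]
    coords: np.ndarray     # (n, dim)
    provenance: str

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if len(self.ids) != self.coords.shape[0]:
            raise ValueError("one coordinate vector per id required")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite latent coordinates")
        self._index = {i: k for k, i in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ValueError("duplicate ids in LatentSpace")

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def get(self, mol_id: str) -> np.ndarray:
        return self.coords[self._index[mol_id]]

    def subset(self, ids: Sequence[str]) -> np.ndarray:
        return self.coords[[self._index[i] for i in ids]]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(",".join(self.ids).encode())
        h.update(np.ascontiguousarray(self.coords).tobytes())
        return h.hexdigest()[:16]


def gaussian_kl(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL(N(mu, exp(logvar)) || N(0, I)) summed over dims, averaged over rows."""
    mu = np.atleast_2d(mu)
    logvar = np.atleast_2d(logvar)
    per_row = 0.5 * np.sum(mu ** 2 + np.exp(logvar) - logvar - 1.0, axis=1)
    return float(per_row.mean())


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40, 40)))


class VaeEmbedder:
    """NumPy VAE over padded SELFIES token index sequences."""

    def __init__(self, cfg: VaeConfig, vocab: TokenVocabulary):
        self.cfg = cfg
        self.vocab = vocab
        self.V = len(vocab)
        self.L = vocab.max_len
        self.sos = self.V  # extra embedding row for the start token
        self.loss_history: list[dict] = []
        self._rng = np.random.default_rng(cfg.seed)
        self._init_params()
        self._init_adam()

    # -- parameters ---------------------------------------------------------
    def _init_params(self) -> None:
        rng = self._rng
        c = self.cfg

        def glorot(shape):
            lim = math.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-lim, lim, size=shape)

        p: dict[str, np.ndarray] = {}
        widths = (self.L * self.V,) + tuple(c.encoder_widths)
        for i in range(len(widths) - 1):
            p[f"enc_W{i}"] = glorot((widths[i], widths[i + 1]))
            p[f"enc_b{i}"] = np.zeros(widths[i + 1])
        p["W_mu"] = glorot((widths[-1], c.latent_dim))
        p["b_mu"] = np.zeros(c.latent_dim)
        p["W_lv"] = glorot((widths[-1], c.latent_dim))
        p["b_lv"] = np.zeros(c.latent_dim)

        p["E"] = 0.1 * rng.standard_normal((self.V + 1, c.embed_dim))
        H = c.gru_hidden
        for l in range(c.gru_layers):
            # the latent vector is re-injected at every decoder step
            in_dim = (c.embed_dim + c.latent_dim) if l == 0 else H
            p[f"h0_W{l}"] = glorot((c.latent_dim, H))
            p[f"h0_b{l}"] = np.zeros(H)
            p[f"Wx{l}"] = glorot((in_dim, 3 * H))
            p[f"Wh{l}"] = glorot((H, 3 * H))
            p[f"bg{l}"] = np.zeros(3 * H)
        p["W_out"] = glorot((H, self.V))
        p["b_out"] = np.zeros(self.V)
        self.params = p

    def _init_adam(self) -> None:
        self._m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._t = 0

    # -- forward pieces -----------------------------------------------------
    def _encode_mu_lv(self, idx: np.ndarray):
        """idx: (B, L) token indices -> (mu, logvar, cache)."""
        B = idx.shape[0]
        x = np.zeros((B, self.L, self.V))
        x[np.arange(B)[:, None], np.arange(self.L)[None, :], idx] = 1.0
        a = x.reshape(B, -1)
        acts = [a]
        n_layers = len(self.cfg.encoder_widths)
        for i in range(n_layers):
            a = a @ self.params[f"enc_W{i}"] + self.params[f"enc_b{i}"]
            a = np.maximum(a, 0.0)
            acts.append(a)
        mu = a @ self.params["W_mu"] + self.params["b_mu"]
        lv = np.clip(a @ self.params["W_lv"] + self.params["b_lv"], -10, 10)
        return mu, lv, acts

    def _gru_step(self, l: int, x: np.ndarray, h_prev: np.ndarray):
        H = self.cfg.gru_hidden
        Wx, Wh, b = self.params[f"Wx{l}"], self.params[f"Wh{l}"], self.params[f"bg{l}"]
        ax = x @ Wx + b
        ahr = h_prev @ Wh[:, :H]
        ahz = h_prev @ Wh[:, H:2 * H]
        r = _sigmoid(ax[:, :H] + ahr)
        z = _sigmoid(ax[:, H:2 * H] + ahz)
        rh = r * h_prev
        an = ax[:, 2 * H:] + rh @ Wh[:, 2 * H:]
        n = np.tanh(an)
        h = (1.0 - z) * n + z * h_prev
        cache = (x, h_prev, r, z, n, rh)
        return h, cache

    def _decoder_forward(self, z: np.ndarray, idx: np.ndarray):
        """Teacher-forced decoding; returns logits (B, L, V) + caches."""
        c = self.cfg
        B = z.shape[0]
        h = []
        h0_caches = []
        for l in range(c.gru_layers):
            pre = z @ self.params[f"h0_W{l}"] + self.params[f"h0_b{l}"]
            hl = np.tanh(pre)
            h.append(hl)
            h0_caches.append(hl)
        inputs = np.concatenate(
            [np.full((B, 1), self.sos, dtype=np.int64), idx[:, :-1]], axis=1)
        logits = np.empty((B, self.L, self.V))
        step_caches: list[list] = []
        tops = []
        for t in range(self.L):
            x = np.concatenate([self.params["E"][inputs[:, t]], z], axis=1)
            caches_t = []
            for l in range(c.gru_layers):
                h[l], cache = self._gru_step(l, x, h[l])
                caches_t.append(cache)
                x = h[l]
            logits[:, t, :] = x @ self.params["W_out"] + self.params["b_out"]
            step_caches.append(caches_t)
            tops.append(x)
        return logits, (inputs, step_caches, tops, h0_caches, z)

    # -- loss + backward ----------------------------------------------------
    def _step(self, idx: np.ndarray, beta: float):
        """One training step on a batch of index sequences; returns losses."""
        B = idx.shape[0]
        c = self.cfg
        H = c.gru_hidden
        mu, lv, enc_acts = self._encode_mu_lv(idx)
        eps = self._rng.standard_normal(mu.shape)
        std = np.exp(0.5 * lv)
        z = mu + eps * std

        logits, dec_cache = self._decoder_forward(z, idx)
        # softmax CE per position, summed over positions, mean over batch
        m = logits.max(axis=2, keepdims=True)
        ex = np.exp(logits - m)
        probs = ex / ex.sum(axis=2, keepdims=True)
        B_idx = np.arange(B)[:, None]
        L_idx = np.arange(self.L)[None, :]
        logp = np.log(probs[B_idx, L_idx, idx] + 1e-12)
        recon = float(-logp.sum(axis=1).mean())
        kl = gaussian_kl(mu, lv)
        loss = recon + beta * kl
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss (recon={recon}, kl={kl})")

        g = {k: np.zeros_like(v) for k, v in self.params.items()}

        # CE gradient
        dlogits = probs.copy()
        dlogits[B_idx, L_idx, idx] -= 1.0
        dlogits /= B

        inputs, step_caches, tops, h0_caches, _ = dec_cache
        dh = [np.zeros((B, H)) for _ in range(c.gru_layers)]
        dE = g["E"]
        dz_steps = np.zeros_like(z)
        for t in range(self.L - 1, -1, -1):
            dtop = dlogits[:, t, :] @ self.params["W_out"].T
            g["W_out"] += tops[t].T @ dlogits[:, t, :]
            g["b_out"] += dlogits[:, t, :].sum(axis=0)
            dh[c.gru_layers - 1] = dh[c.gru_layers - 1] + dtop
            dx_upper = None
            for l in range(c.gru_layers - 1, -1, -1):
                if dx_upper is not None:
                    dh[l] = dh[l] + dx_upper
                x, h_prev, r, zg, n, rh = step_caches[t][l]
                Wx, Wh = self.params[f"Wx{l}"], self.params[f"Wh{l}"]
                dh_l = dh[l]
                dn = dh_l * (1.0 - zg)
                dzg = dh_l * (h_prev - n)
                dh_prev = dh_l * zg
                dan = dn * (1.0 - n ** 2)
                daz = dzg * zg * (1.0 - zg)
                gn = dan @ Wh[:, 2 * H:].T
                dr = gn * h_prev
                dh_prev = dh_prev + gn * r
                dar = dr * r * (1.0 - r)
                dh_prev = dh_prev + dar @ Wh[:, :H].T + daz @ Wh[:, H:2 * H].T
                da = np.concatenate([dar, daz, dan], axis=1)
                dx = da @ Wx.T
                g[f"Wx{l}"] += x.T @ da
                g[f"bg{l}"] += da.sum(axis=0)
                g[f"Wh{l}"][:, :H] += h_prev.T @ dar
                g[f"Wh{l}"][:, H:2 * H] += h_prev.T @ daz
                g[f"Wh{l}"][:, 2 * H:] += rh.T @ dan
                dh[l] = dh_prev
                dx_upper = dx
            np.add.at(dE, inputs[:, t], dx_upper[:, :c.embed_dim])
            dz_steps += dx_upper[:, c.embed_dim:]

        # initial hidden states -> latent
        dz = dz_steps
        for l in range(c.gru_layers):
            hl = h0_caches[l]
            dpre = dh[l] * (1.0 - hl ** 2)
            g[f"h0_W{l}"] += z.T @ dpre
            g[f"h0_b{l}"] += dpre.sum(axis=0)
            dz += dpre @ self.params[f"h0_W{l}"].T

        # reparameterization + KL
        dmu = dz + beta * mu / B
        dlv = dz * eps * 0.5 * std + beta * 0.5 * (np.exp(lv) - 1.0) / B

        # encoder backward
        a_last = enc_acts[-1]
        g["W_mu"] += a_last.T @ dmu
        g["b_mu"] += dmu.sum(axis=0)
        g["W_lv"] += a_last.T @ dlv
        g["b_lv"] += dlv.sum(axis=0)
        da = dmu @ self.params["W_mu"].T + dlv @ self.params["W_lv"].T
        for i in range(len(c.encoder_widths) - 1, -1, -1):
            da = da * (enc_acts[i + 1] > 0)
            g[f"enc_W{i}"] += enc_acts[i].T @ da
            g[f"enc_b{i}"] += da.sum(axis=0)
            da = da @ self.params[f"enc_W{i}"].T

        self._adam_update(g)
        return loss, recon, kl

    def _adam_update(self, grads, b1=0.9, b2=0.999, eps=1e-8):
        self._t += 1
        lr = self.cfg.learning_rate
        for k, gk in grads.items():
            self._m[k] = b1 * self._m[k] + (1 - b1) * gk
            self._v[k] = b2 * self._v[k] + (1 - b2) * gk ** 2
            mhat = self._m[k] / (1 - b1 ** self._t)
            vhat = self._v[k] / (1 - b2 ** self._t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- public API ---------------------------------------------------------
    def fit(self, sequences: np.ndarray) -> "VaeEmbedder":
        """Train on an (n, max_len) array of padded token indices."""
        n = sequences.shape[0]
        if n == 0:
            raise chemlib.InputError("empty training set")
        c = self.cfg
        warm = max(1, int(round(c.kl_warmup_frac * c.epochs)))
        for epoch in range(c.epochs):
            beta = c.kl_weight * min(1.0, (epoch + 1) / warm)
            perm = self._rng.permutation(n)
            tot = rec = kl = 0.0
            nb = 0
            for start in range(0, n, c.batch_size):
                batch = sequences[perm[start:start + c.batch_size]]
                l, r, k = self._step(batch, beta)
                tot += l; rec += r; kl += k; nb += 1
            self.loss_history.append(
                {"epoch": epoch, "loss": tot / nb, "recon": rec / nb,
                 "kl": kl / nb, "beta": beta})
        return self

    def encode_sequences(self, sequences: np.ndarray) -> np.ndarray:
        """Posterior-mean latent coordinates (deterministic)."""
        mu, _, _ = self._encode_mu_lv(np.atleast_2d(sequences))
        return mu

    def decode_latent(self, z: np.ndarray) -> list[list[str]]:
        """Greedy (argmax) free-running decode of latent vectors to tokens."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.cfg.latent_dim:
            raise ValueError(f"latent dim {z.shape[1]} != {self.cfg.latent_dim}")
        c = self.cfg
        B = z.shape[0]
        h = [np.tanh(z @ self.params[f"h0_W{l}"] + self.params[f"h0_b{l}"])
             for l in range(c.gru_layers)]
        tok = np.full(B, self.sos, dtype=np.int64)
        out = np.empty((B, self.L), dtype=np.int64)
        for t in range(self.L):
            x = np.concatenate([self.params["E"][tok], z], axis=1)
            for l in range(c.gru_layers):
                h[l], _ = self._gru_step(l, x, h[l])
                x = h[l]
            logits = x @ self.params["W_out"] + self.params["b_out"]
            tok = logits.argmax(axis=1)
            out[:, t] = tok
        return [self.vocab.from_indices(row, strip_pad=True) for row in out]


def sequences_for(molecules: Sequence[Molecule],
                  vocab: TokenVocabulary) -> tuple[list[str], np.ndarray]:
    """Padded index sequences for all SELFIES-encodable molecules."""
    ids, rows = [], []
    for m in molecules:
        if not m.encodable:
            continue
        rows.append(vocab.to_indices(m.selfies_tokens, pad=True))
        ids.append(m.id)
    if not rows:
        raise chemlib.InputError("no encodable molecules")
    return ids, np.stack(rows)


def train_vae(library: CandidateLibrary, cfg: VaeConfig,
              vocab: Optional[TokenVocabulary] = None) -> VaeEmbedder:
    """Train the VAE once over the library; the embedder is then frozen.

    Deterministic given ``cfg.seed``; loss history is recorded per epoch and
    a non-finite loss aborts with diagnostics.
    """
    if len(library) == 0:
        raise chemlib.InputError("empty library")
    if vocab is None:
        vocab = TokenVocabulary.from_molecules(library.molecules)
    _, seqs = sequences_for(library.molecules, vocab)
    embedder = VaeEmbedder(cfg, vocab)
    embedder.fit(seqs)
    return embedder


def encode(embedder: VaeEmbedder, molecules: Sequence[Molecule]) -> LatentSpace:
    """Posterior-mean coordinates for every encodable molecule.

    Molecules that cannot be tokenized within the vocabulary are collected in
    a rejects report attached as ``latent_space_rejects``.
    """
    ids, rows, rejects = [], [], []
    for m in molecules:
        try:
            if not m.encodable:
                raise chemlib.EncodingError(m.selfies_error or "not encodable")
            rows.append(embedder.vocab.to_indices(m.selfies_tokens, pad=True))
            ids.append(m.id)
        except chemlib.EncodingError as exc:
            rejects.append({"id": m.id, "reason": str(exc)})
    if not rows:
        raise chemlib.InputError("no encodable molecules")
    coords = embedder.encode_sequences(np.stack(rows))
    space = LatentSpace(ids=ids, coords=coords,
                        provenance=f"VAE({embedder.cfg.hash()})")
    space.rejects = rejects
    return space


def decode(embedder: VaeEmbedder, z: np.ndarray) -> list[str]:
    """Greedy decode of one latent vector to a SELFIES token sequence."""
    return embedder.decode_latent(np.atleast_2d(z))[0]


def reconstruction_accuracy(embedder: VaeEmbedder,
                            molecules: Sequence[Molecule]) -> float:
    """Fraction of molecules whose greedy decode of the posterior mean
    reproduces the canonical SMILES exactly."""
    mols = [m for m in molecules if m.encodable]
    ids, seqs = sequences_for(mols, embedder.vocab)
    z = embedder.encode_sequences(seqs)
    decoded = embedder.decode_latent(z)
    hits = 0
    for m, toks in zip(mols, decoded):
        try:
            if chemlib.decode_selfies(toks) == m.smiles:
                hits += 1
        except Exception:
            pass
    return hits / len(mols)


def fingerprint_embedding(molecules: Sequence[Molecule],
                          n_bits: int = 2048) -> LatentSpace:
    """ECFP4 bit vectors cast to reals; drop-in replacement for VAE coords."""
    ids = [m.id for m in molecules]
    coords = np.stack([chemlib.ecfp4_fingerprint(m, n_bits) for m in molecules]
                      ).astype(np.float64)
    return LatentSpace(ids=ids, coords=coords,
                       provenance=f"FINGERPRINT({n_bits})")
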