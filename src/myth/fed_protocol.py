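"""In-process federation: client shards, server averaging, scheduling.

Two sharing schemes are supported:

* ``gm`` — the server averages all learnable parameters (conv layers,
  prototypes, final layer);
* ``pm`` — only the prototypes and final-layer weights are averaged; the
  feature-extraction layers always stay local.  Training finishes with a
  per-client prototype push and a final-layer-only refit (personalization).

Transport is simulated in-process: the shared subset of each client's
parameters is extracted into a plain dict ("upload"), averaged, and
installed back ("broadcast").  An optional ``on_upload`` hook observes every
message the server would receive, which the tests use to assert the privacy
contract.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .errors import ConfigurationError, FederationError, ValidationError
from .model_core import (ModelParams, PrototypeSet, TrainConfig, loss,
                         train_final_layer_only, train_local)
from .projection_viz import push_prototypes

SCHEMES = ('gm', 'pm')


@dataclass
class FederationConfig:
    n_clients: int = 4
    rounds: int = 4
    warmup_epochs: int = 5
    epochs_per_round: int = 10
    scheme: str = 'gm'
    seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)
    personalize_epochs: int = 10   # final-layer refit length under pm

    def __post_init__(self):
        if self.n_clients < 1:
            raise ConfigurationError("n_clients must be >= 1")
        if self.rounds < 1:
            raise ConfigurationError("rounds must be >= 1")
        if self.warmup_epochs < 0:
            raise ConfigurationError("warmup_epochs must be >= 0")
        if self.epochs_per_round < 1:
            raise ConfigurationError("epochs_per_round must be >= 1")
        if self.scheme not in SCHEMES:
            raise ConfigurationError(f"scheme must be one of {SCHEMES}")


@dataclass
class GlobalParams:
    prototypes_glob: PrototypeSet
    final_glob: np.ndarray
    conv_glob: Optional[dict] = None   # present only under scheme gm


@dataclass
class ClientState:
    client_id: int
    params: ModelParams
    train_shard: list


def _shared_subset(params: ModelParams, scheme: str) -> dict:
    """The parameter message a client uploads to the server."""
    msg = {
        'prototypes': params.prototypes.vectors.copy(),
        'final_weights': params.final_weights.copy(),
    }
    if scheme == 'gm':
        msg['conv_weights'] = {k: v.copy() for k, v in params.conv_weights.items()}
    return msg


def _mean(arrays):
    # anchored at the first array so averaging identical inputs is bit-exact
    base = arrays[0]
    return base + sum(a - base for a in arrays[1:]) / len(arrays)


def average_params(client_params, scheme: str) -> GlobalParams:
    """Unweighted elementwise mean of the shared parameter subset."""
    if scheme not in SCHEMES:
        raise ConfigurationError(f"scheme must be one of {SCHEMES}")
    if len(client_params) == 0:
        raise FederationError("no client parameters to average")
    ref = client_params[0]
    for p in client_params[1:]:
        if p.prototypes.vectors.shape != ref.prototypes.vectors.shape:
            raise FederationError("prototype shape mismatch across clients")
        if not np.array_equal(p.prototypes.class_of, ref.prototypes.class_of):
            raise FederationError("prototype class maps differ across clients")
        if p.final_weights.shape != ref.final_weights.shape:
            raise FederationError("final-layer shape mismatch across clients")
    proto_mean = _mean([p.prototypes.vectors for p in client_params])
    final_mean = _mean([p.final_weights for p in client_params])
    conv_mean = None
    if scheme == 'gm':
        keys = set(ref.conv_weights)
        for p in client_params[1:]:
            if set(p.conv_weights) != keys:
                raise FederationError("conv parameter sets differ across clients")
        conv_mean = {k: _mean([p.conv_weights[k] for p in client_params])
                     for k in keys}
    return GlobalParams(
        prototypes_glob=PrototypeSet(proto_mean, ref.prototypes.class_of.copy(),
                                     ref.prototypes.per_class),
        final_glob=final_mean,
        conv_glob=conv_mean,
    )


def install_global(params: ModelParams, glob: GlobalParams, scheme: str) -> None:
    """Overwrite a client's shared parameter subset with the global values."""
    if glob.prototypes_glob.vectors.shape != params.prototypes.vectors.shape:
        raise FederationError("global prototype shape mismatch")
    params.prototypes.vectors = glob.prototypes_glob.vectors.copy()
    params.final_weights = glob.final_glob.copy()
    if scheme == 'gm':
        if glob.conv_glob is None:
            raise FederationError("scheme gm requires global conv weights")
        params.conv_weights = {k: v.copy() for k, v in glob.conv_glob.items()}


def run_round(clients, glob: Optional[GlobalParams], cfg: FederationConfig,
              epoch_offset: int = 0, frozen: bool = False,
              on_upload: Optional[Callable] = None):
    """One communication round: broadcast, local training, aggregation."""
    epochs = cfg.warmup_epochs if frozen else cfg.epochs_per_round
    if epochs < 1:
        raise ConfigurationError("round with no local epochs")
    uploads = []
    for client in clients:
        if glob is not None:
            install_global(client.params, glob, cfg.scheme)
        tcfg = cfg.train.replace(epochs=epochs, frozen_backbone=frozen,
                                 seed=cfg.train.seed + client.client_id)
        try:
            client.params = train_local(client.train_shard, client.params, tcfg,
                                        epoch_offset=epoch_offset)
        except Exception as exc:
            raise FederationError(
                f"client {client.client_id} failed during local training: {exc}"
            ) from exc
        msg = _shared_subset(client.params, cfg.scheme)
        if on_upload is not None:
            on_upload(client.client_id, msg)
        uploads.append(client.params)
    new_glob = average_params(uploads, cfg.scheme)
    return clients, new_glob


def run_federation(shards, init_params: ModelParams, cfg: FederationConfig,
                   on_upload: Optional[Callable] = None,
                   eval_fn: Optional[Callable] = None):
    """Warm-up round plus cfg.rounds full communication rounds.

    The server initializes one model and sends it to every client; the
    warm-up trains with the backbone frozen for cfg.warmup_epochs epochs and
    aggregates; each subsequent round trains all layers locally for
    cfg.epochs_per_round epochs before aggregation.

    Returns (GlobalParams, list of ClientState, history) where history holds
    one record per (round, client) with the training loss and optional eval
    metrics from eval_fn(client).
    """
    if len(shards) != cfg.n_clients:
        raise ConfigurationError(
            f"got {len(shards)} shards for {cfg.n_clients} clients")
    clients = [ClientState(client_id=i, params=init_params.copy(), train_shard=s)
               for i, s in enumerate(shards)]
    history = []
    glob = None
    offset = 0
    if cfg.warmup_epochs > 0:
        clients, glob = run_round(clients, None, cfg, epoch_offset=0,
                                  frozen=True, on_upload=on_upload)
        offset = cfg.warmup_epochs
        _log_round(history, -1, clients, cfg, eval_fn)
    for r in range(cfg.rounds):
        clients, glob = run_round(clients, glob, cfg, epoch_offset=offset,
                                  frozen=False, on_upload=on_upload)
        offset += cfg.epochs_per_round
        _log_round(history, r, clients, cfg, eval_fn)
    return glob, clients, history


def _log_round(history, round_id, clients, cfg, eval_fn):
    for client in clients:
        rec = {'round': round_id, 'client': client.client_id,
               'train_loss': float(loss(client.train_shard, client.params,
                                        cfg.train))}
        if eval_fn is not None:
            rec.update(eval_fn(client))
        history.append(rec)


def personalize(client: ClientState, prototypes_glob: PrototypeSet,
                final_glob: np.ndarray, train_shard, cfg: FederationConfig
                ) -> ModelParams:
    """PM finishing step for one client.

    Installs the global prototypes and final layer, pushes each prototype
    onto the nearest same-class latent patch of the client's own shard, then
    refits only the final layer.  Conv weights and pushed prototypes are
    untouched by the refit.
    """
    if len(train_shard) == 0:
        raise ValidationError("empty training shard")
    params = client.params.copy()
    install_global(params, GlobalParams(prototypes_glob, final_glob), 'pm')
    pushed, _ = push_prototypes(params, train_shard)
    tcfg = cfg.train.replace(epochs=max(cfg.personalize_epochs, 1))
    return train_final_layer_only(train_shard, pushed, tcfg)
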