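"""End-to-end staged pipelines for the three models.

Each model trains front end -> mid stage -> output stage in order, with
earlier stages frozen (enforced by weight hashing):

* model 1: direction mosaic (DSMN) -> cell planes (CPNW) -> 4-class
  perceptron on optic-flow sequences;
* model 2: DSMN -> winner-take-all Hebbian net (HBNW) -> MLP on optic-flow
  sequences;
* model 3: velocity mosaic (VSMN) -> CNN on the 8-class flow x speed task,
  plus conv1/fc4 linear probes;
* speed variant: models 1-2 with the VSMN front end on the two-speed flow
  task (8 classes).

Two parameter profiles ship: ``full`` uses the complete epoch counts and
independent DSMN tiles; ``fast`` shares tile weights and divides epochs by
five for desk-scale runs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np

from . import analysis, classifiers as cl, midstage as ms, mosaic as mo
from . import neural_field as nf
from . import stimuli


class StageGeometryError(ValueError):
    """Configured stages do not fit together."""


@dataclass(frozen=True)
class Profile:
    """Epoch counts and sharing flags for one experiment scale."""

    name: str
    dsmn_tile: nf.FieldParams
    vsmn_tile: nf.FieldParams
    dsmn_share: bool
    cpnw_epochs: int
    hbnw_epochs: int
    perceptron_epochs: int
    mlp_epochs: int
    cnn_epochs: int
    n_configs: int = 15


FULL = Profile(
    name="full",
    dsmn_tile=nf.DSMN_TILE,
    vsmn_tile=nf.VSMN_TILE,
    dsmn_share=False,
    cpnw_epochs=1000,
    hbnw_epochs=10000,
    perceptron_epochs=500,
    mlp_epochs=5000,
    cnn_epochs=350,
)

FAST = Profile(
    name="fast",
    dsmn_tile=replace(nf.DSMN_TILE, epochs=nf.DSMN_TILE.epochs // 5),
    vsmn_tile=replace(nf.VSMN_TILE, epochs=nf.VSMN_TILE.epochs // 5),
    dsmn_share=True,
    cpnw_epochs=200,
    hbnw_epochs=2000,
    perceptron_epochs=100,
    mlp_epochs=1000,
    cnn_epochs=70,
)


def get_profile(name: str) -> Profile:
    try:
        return {"full": FULL, "fast": FAST}[name]
    except KeyError:
        raise ValueError(f"unknown profile {name!r}") from None


def _seeds(seed, n):
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


def weight_hash(obj) -> str:
    """SHA-256 over all weight arrays of a mosaic or net (freeze checks)."""
    h = hashlib.sha256()
    if isinstance(obj, mo.Mosaic):
        for st in obj.tiles:
            h.update(np.ascontiguousarray(st.W_aff).tobytes())
            h.update(st.E.data.tobytes())
            h.update(st.I.data.tobytes())
    elif isinstance(obj, (ms.CellPlaneNet, ms.HebbNet)):
        h.update(np.ascontiguousarray(obj.W).tobytes())
    else:
        raise TypeError(f"no weight hash for {type(obj)}")
    return h.hexdigest()


def train_frontend(model_id: int, profile: Profile, seed) -> mo.Mosaic:
    """Train the DSMN (models 1-2) or VSMN (model 3 / speed variant)."""
    local = stimuli.local_training_set(model_id)
    if model_id in (1, 2):
        cfg = mo.MosaicConfig(16, profile.dsmn_tile, profile.dsmn_share)
    else:
        cfg = mo.MosaicConfig(10, profile.vsmn_tile, share_weights=True)
    return mo.train_mosaic(cfg, local, seed)


def responses_for(mosaic, dataset: stimuli.StimulusSet):
    """Front-end responses for every train and test sequence of a dataset."""
    train = mo.mosaic_responses(mosaic, dataset.train)
    test = mo.mosaic_responses(mosaic, dataset.test)
    return train, test


def run_model1(
    dsmn: mo.Mosaic,
    trans_train, trans_labels,
    trans_test, trans_test_labels,
    flow_train, flow_labels,
    flow_test, flow_test_labels,
    profile: Profile,
    seed,
) -> dict:
    """CPNW on translational responses, then the flow perceptron."""
    s_cpnw, s_perc = _seeds(seed, 2)
    front_hash = weight_hash(dsmn)
    net = ms.cpnw_train(
        trans_train, trans_labels,
        epochs=profile.cpnw_epochs, seed=s_cpnw, grid=dsmn.config.grid,
    )
    cpnw_train_acc = ms.cpnw_accuracy(net, trans_train, trans_labels)
    cpnw_test_acc = ms.cpnw_accuracy(net, trans_test, trans_test_labels)

    mid_hash = weight_hash(net)
    Xtr = np.stack([ms.cpnw_feature_vector(net, z) for z in flow_train])
    Xte = np.stack([ms.cpnw_feature_vector(net, z) for z in flow_test])
    n_classes = len(np.unique(flow_labels))
    perc = cl.perceptron_train(
        Xtr, flow_labels, epochs=profile.perceptron_epochs, seed=s_perc,
        classes=np.arange(n_classes),
    )
    report = {
        "cpnw_train_accuracy": cpnw_train_acc,
        "cpnw_test_accuracy": cpnw_test_acc,
        "flow_train_accuracy": cl.perceptron_accuracy(perc, Xtr, flow_labels),
        "flow_test_accuracy": cl.perceptron_accuracy(perc, Xte, flow_test_labels),
    }
    assert weight_hash(dsmn) == front_hash, "front-end weights changed"
    assert weight_hash(net) == mid_hash, "mid-stage weights changed"
    report["cpnw"] = net
    report["perceptron"] = perc
    return report



def _standardize(Xtr, Xte):
    """Z-score features on the training split (conditioning for the MLP:
    mid-stage sigmoid activities occupy a narrow band around 0.5)."""
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    return (Xtr - mu) / sd, (Xte - mu) / sd


def run_model2(
    dsmn: mo.Mosaic,
    trans_train, trans_labels,
    flow_train, flow_labels,
    flow_test, flow_test_labels,
    profile: Profile,
    seed,
    mlp_hidden=(256, 156, 50),
) -> dict:
    """HBNW by competitive learning, then the flow MLP."""
    s_hbnw, s_mlp = _seeds(seed, 2)
    front_hash = weight_hash(dsmn)
    net = ms.hbnw_train(
        trans_train, epochs=profile.hbnw_epochs, seed=s_hbnw,
        grid=dsmn.config.grid,
    )
    mid_hash = weight_hash(net)
    Xtr = np.stack([ms.hbnw_feature_vector(net, z) for z in flow_train])
    Xte = np.stack([ms.hbnw_feature_vector(net, z) for z in flow_test])
    Xtr, Xte = _standardize(Xtr, Xte)
    n_classes = len(np.unique(flow_labels))
    sizes = (Xtr.shape[1], *mlp_hidden, n_classes)
    mlp = cl.mlp_train(
        Xtr, flow_labels, layer_sizes=sizes,
        epochs=profile.mlp_epochs, seed=s_mlp,
    )
    report = {
        "flow_train_accuracy": cl.mlp_accuracy(mlp, Xtr, flow_labels),
        "flow_test_accuracy": cl.mlp_accuracy(mlp, Xte, flow_test_labels),
    }
    assert weight_hash(dsmn) == front_hash, "front-end weights changed"
    assert weight_hash(net) == mid_hash, "mid-stage weights changed"
    report["hbnw"] = net
    report["mlp"] = mlp
    return report


def run_model3(
    vsmn: mo.Mosaic,
    flow_ds: stimuli.StimulusSet,
    flow_train, flow_test,
    trans_ds: stimuli.StimulusSet | None = None,
    trans_train=None, trans_test=None,
    profile: Profile = FAST,
    seed=0,
) -> dict:
    """Train the CNN on VSMN flow responses; optionally run the probes."""
    s_cnn, s_probe = _seeds(seed, 2)
    front_hash = weight_hash(vsmn)
    Xtr = np.stack([r.concat for r in flow_train]).astype(np.float32)
    Xte = np.stack([r.concat for r in flow_test]).astype(np.float32)
    cfg = cl.CNNConfig(epochs=profile.cnn_epochs)
    cnn = cl.cnn_train(Xtr, flow_ds.train_labels, cfg, seed=s_cnn)
    report = {
        "cnn_train_accuracy": cl.cnn_accuracy(cnn, Xtr, flow_ds.train_labels),
        "cnn_test_accuracy": cl.cnn_accuracy(cnn, Xte, flow_ds.test_labels),
        "confusion": _confusion(
            cnn.predict(Xte), flow_ds.test_labels, cfg.n_classes
        ),
    }
    assert weight_hash(vsmn) == front_hash, "front-end weights changed"
    report["cnn"] = cnn

    if trans_ds is not None:
        report["probes"] = probe_suite(
            cnn, flow_ds, flow_train, flow_test,
            trans_ds, trans_train, trans_test, seed=s_probe,
        )
    return report


def _confusion(pred, true, k):
    M = np.zeros((k, k), dtype=int)
    for t, p in zip(true, pred):
        M[t, p] += 1
    return M


def _activations(cnn: cl.CNN, resps, batch=32):
    conv, fc4 = [], []
    for i in range(0, len(resps), batch):
        X = np.stack([r.concat for r in resps[i : i + batch]]).astype(np.float32)
        acts = cnn.layer_activations(X)
        conv.append(acts["conv1"].reshape(len(X), -1))
        fc4.append(acts["fc4"])
    return np.concatenate(conv), np.concatenate(fc4)


def probe_suite(
    cnn: cl.CNN,
    flow_ds, flow_train, flow_test,
    trans_ds, trans_train, trans_test,
    seed=0,
    speed: int = 1,
) -> dict:
    """The four conv1/fc4 linear probes on the speed-``speed`` subsets.

    Translational probes decode the 8 directions; flow probes decode the 4
    flow types.  Labels 0-7 are speed-1 classes, 8-15 (translational) or
    4-7 (flow) speed-2, so the speed subset is a label range.
    """
    s = _seeds(seed, 4)
    conv_f, fc4_f = _activations(cnn, list(flow_train) + list(flow_test))
    y_f = np.concatenate([flow_ds.train_labels, flow_ds.test_labels])
    m_f = np.concatenate(
        [np.ones(len(flow_ds.train_labels), bool), np.zeros(len(flow_ds.test_labels), bool)]
    )
    conv_t, fc4_t = _activations(cnn, list(trans_train) + list(trans_test))
    y_t = np.concatenate([trans_ds.train_labels, trans_ds.test_labels])
    m_t = np.concatenate(
        [np.ones(len(trans_ds.train_labels), bool), np.zeros(len(trans_ds.test_labels), bool)]
    )

    lo, hi = (0, 4) if speed == 1 else (4, 8)
    sel_f = (y_f >= lo) & (y_f < hi)
    lo_t, hi_t = (0, 8) if speed == 1 else (8, 16)
    sel_t = (y_t >= lo_t) & (y_t < hi_t)

    return {
        "conv1_translational": analysis.probe_classifier(
            conv_t[sel_t], y_t[sel_t], m_t[sel_t], seed=s[0]
        ),
        "fc4_translational": analysis.probe_classifier(
            fc4_t[sel_t], y_t[sel_t], m_t[sel_t], seed=s[1]
        ),
        "conv1_flow": analysis.probe_classifier(
            conv_f[sel_f], y_f[sel_f], m_f[sel_f], seed=s[2]
        ),
        "fc4_flow": analysis.probe_classifier(
            fc4_f[sel_f], y_f[sel_f], m_f[sel_f], seed=s[3]
        ),
    }


def run_speed_variant(
    model_id: int,
    vsmn: mo.Mosaic,
    flow_ds: stimuli.StimulusSet,
    flow_train, flow_test,
    profile: Profile,
    seed,
    trans_train=None, trans_labels=None,
) -> dict:
    """Models 1-2 with the velocity front end on the 8-class flow-speed task.

    The mid stage keeps its 8 channels and is retrained on the two-speed
    stimuli; only the output stage grows to 8 classes.
    """
    if model_id not in (1, 2):
        raise ValueError("speed variant applies to models 1 and 2")
    s_mid, s_out = _seeds(seed, 2)
    grid = vsmn.config.grid
    if model_id == 1:
        if trans_train is None:
            raise ValueError("model-1 variant needs per-direction translational responses")
        dir_labels = np.asarray(trans_labels) % 8  # collapse speeds onto direction
        net = ms.cpnw_train(
            trans_train, dir_labels, epochs=profile.cpnw_epochs,
            seed=s_mid, grid=grid,
        )
        Xtr = np.stack([ms.cpnw_feature_vector(net, z) for z in flow_train])
        Xte = np.stack([ms.cpnw_feature_vector(net, z) for z in flow_test])
        out = cl.perceptron_train(
            Xtr, flow_ds.train_labels, epochs=profile.perceptron_epochs,
            seed=s_out, classes=np.arange(8),
        )
        train_acc = cl.perceptron_accuracy(out, Xtr, flow_ds.train_labels)
        test_acc = cl.perceptron_accuracy(out, Xte, flow_ds.test_labels)
    else:
        net = ms.hbnw_train(
            flow_train, epochs=profile.hbnw_epochs, seed=s_mid, grid=grid,
        )
        Xtr = np.stack([ms.hbnw_feature_vector(net, z) for z in flow_train])
        Xte = np.stack([ms.hbnw_feature_vector(net, z) for z in flow_test])
        Xtr, Xte = _standardize(Xtr, Xte)
        mlp = cl.mlp_train(
            Xtr, flow_ds.train_labels, layer_sizes=(Xtr.shape[1], 256, 156, 50, 8),
            epochs=profile.mlp_epochs, seed=s_out,
        )
        train_acc = cl.mlp_accuracy(mlp, Xtr, flow_ds.train_labels)
        test_acc = cl.mlp_accuracy(mlp, Xte, flow_ds.test_labels)
    return {"train_accuracy": train_acc, "test_accuracy": test_acc}


def run_model(model_id: int, profile: Profile | str = FAST, seed=0) -> dict:
    """Full staged run of one model from scratch."""
    if isinstance(profile, str):
        profile = get_profile(profile)
    s_front, s_data, s_stage = _seeds(seed, 3)
    front = train_frontend(model_id, profile, s_front)
    if model_id in (1, 2):
        trans = stimuli.build_dataset(model_id, "translational", profile.n_configs, s_data)
        flow = stimuli.build_dataset(model_id, "flow", profile.n_configs, s_data)
        ttr, tte = responses_for(front, trans)
        ftr, fte = responses_for(front, flow)
        if model_id == 1:
            rep = run_model1(
                front, ttr, trans.train_labels, tte, trans.test_labels,
                ftr, flow.train_labels, fte, flow.test_labels, profile, s_stage,
            )
        else:
            rep = run_model2(
                front, ttr, trans.train_labels,
                ftr, flow.train_labels, fte, flow.test_labels, profile, s_stage,
            )
    else:
        flow = stimuli.build_dataset(3, "flow", profile.n_configs, s_data)
        trans = stimuli.build_dataset(3, "translational", profile.n_configs, s_data)
        ftr, fte = responses_for(front, flow)
        ptr, pte = responses_for(front, trans)
        rep = run_model3(
            front, flow, ftr, fte, trans, ptr, pte, profile, s_stage,
        )
    rep["model_id"] = model_id
    rep["profile"] = profile.name
    rep["seed"] = seed
    rep["frontend"] = front
    return rep
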