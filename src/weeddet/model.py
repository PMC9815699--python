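"""Desk-scale single-stage crop/weed detector.

A width/depth-configurable YOLO-style network: a cross-stage-partial (CSP)
backbone optionally finished with a transformer encoder block, a PANet-style
top-down/bottom-up neck whose top lateral is optionally bridged by the CFFI
block, and a three-scale anchor-based head whose per-level inputs are
optionally ASFF-fused from all three neck outputs.  The three toggles are
independent so the ablation grid (baseline, +transformer, +CFFI,
+transformer+CFFI, full) is constructible from one config type.

Defaults are desk-scale: ~96-160 px inputs and a 0.125 width multiple, so a
forward pass and a short training run fit on one CPU; full-scale reference
channel counts (64...1024 backbone, 768 for CFFI) are scaled by the width
multiple.  There is no batch normalisation (convolutions carry biases), no
pretraining, and the optimizer is plain SGD with momentum — training here is
a correctness exercise, not a benchmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Module, Tensor
from .nnblocks import (
    ASFFHead,
    CFFI,
    Conv,
    InvolutionConfig,
    TransformerConfig,
    TransformerEncoder,
)
from .synthdata import AnnotatedImage

DEFAULT_ANCHORS = (
    ((5.0, 5.0), (8.0, 8.0), (12.0, 12.0)),       # stride 8
    ((14.0, 14.0), (19.0, 19.0), (26.0, 26.0)),   # stride 16
    ((32.0, 32.0), (44.0, 44.0), (60.0, 60.0)),   # stride 32
)


class NonFiniteLossError(RuntimeError):
    pass


@dataclass
class ModelConfig:
    input_size: int = 96
    width_multiple: float = 0.125
    depth_multiple: float = 0.33
    n_classes: int = 2
    anchors: tuple = DEFAULT_ANCHORS
    strides: tuple[int, int, int] = (8, 16, 32)
    use_transformer: bool = False
    use_cffi: bool = False
    use_asff: bool = False
    n_transformer_blocks: int = 1
    interpolation: str = "nearest"
    seed: int = 0

    def __post_init__(self):
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if len(self.anchors) != 3 or len(self.strides) != 3:
            raise ValueError("exactly three prediction levels are required")
        for level in self.anchors:
            for w, h in level:
                if w <= 0 or h <= 0:
                    raise ValueError("anchors must be positive")

    def ch(self, full_scale: int) -> int:
        """Scale a full-scale channel count by the width multiple (min 4,
        multiples of 4)."""
        return max(4, int(round(full_scale * self.width_multiple / 4)) * 4)

    @property
    def n_anchors(self) -> int:
        return len(self.anchors[0])

    @property
    def n_outputs(self) -> int:
        return 5 + self.n_classes


@dataclass
class TrainState:
    epochs: list[int] = field(default_factory=list)
    box_loss: list[float] = field(default_factory=list)
    obj_loss: list[float] = field(default_factory=list)
    cls_loss: list[float] = field(default_factory=list)
    total_loss: list[float] = field(default_factory=list)
    val_map50: list[float | None] = field(default_factory=list)
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def log_lines(self) -> str:
        lines = ["epoch\tbox\tobj\tcls\ttotal\tval_map50"]
        for i, e in enumerate(self.epochs):
            v = self.val_map50[i]
            lines.append(
                f"{e}\t{self.box_loss[i]:.6f}\t{self.obj_loss[i]:.6f}"
                f"\t{self.cls_loss[i]:.6f}\t{self.total_loss[i]:.6f}"
                f"\t{'NA' if v is None else f'{v:.4f}'}")
        return "\n".join(lines)


@dataclass
class DetectionSet:
    """Scored class-labeled boxes for one image, pixel corner coordinates."""

    boxes: list[tuple[int, float, float, float, float, float]]
    image_id: str = ""

    def __post_init__(self):
        for cls, conf, x1, y1, x2, y2 in self.boxes:
            if not (x1 < x2 and y1 < y2):
                raise ValueError(f"degenerate box {(x1, y1, x2, y2)}")


# ------------------------------------------------------------------ blocks
class Bottleneck(Module):
    def __init__(self, rng, c: int, shortcut: bool = True):
        self.cv1 = Conv(rng, c, c, k=1)
        self.cv2 = Conv(rng, c, c, k=3)
        self.shortcut = shortcut

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y


class C3(Module):
    """CSP block: two parallel 1x1 projections, one through n bottlenecks."""

    def __init__(self, rng, c_in: int, c_out: int, n: int = 1,
                 inner: list[Module] | None = None):
        c_h = c_out // 2
        self.cv1 = Conv(rng, c_in, c_h, k=1)
        self.cv2 = Conv(rng, c_in, c_h, k=1)
        self.cv3 = Conv(rng, 2 * c_h, c_out, k=1)
        self.blocks = inner if inner is not None else [
            Bottleneck(rng, c_h) for _ in range(n)]

    def forward(self, x):
        a = self.cv1(x)
        for blk in self.blocks:
            a = blk(a)
        return self.cv3(ad.concat([a, self.cv2(x)], axis=1))


class Detector(Module):
    """The assembled detector; see module docstring."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.ch
        n_rep = max(1, round(3 * config.depth_multiple))

        c1, c2, c3, c4, c5 = c(64), c(128), c(256), c(512), c(1024)
        self.c3_channels, self.c4_channels, self.c5_channels = c3, c4, c5

        # backbone (strides 2, 4, 8, 16, 32)
        self.stem = Conv(rng, 3, c1, k=3, stride=2)
        self.down1 = Conv(rng, c1, c2, k=3, stride=2)
        self.csp1 = C3(rng, c2, c2, n_rep)
        self.down2 = Conv(rng, c2, c3, k=3, stride=2)
        self.csp2 = C3(rng, c3, c3, n_rep)
        self.down3 = Conv(rng, c3, c4, k=3, stride=2)
        self.csp3 = C3(rng, c4, c4, n_rep)
        self.down4 = Conv(rng, c4, c5, k=3, stride=2)
        if config.use_transformer:
            tcfg = TransformerConfig(embed_dim=c5 // 2, n_heads=2,
                                     use_positional_embedding=False)
            inner = [TransformerEncoder(tcfg, rng)
                     for _ in range(config.n_transformer_blocks)]
            self.csp4 = C3(rng, c5, c5, inner=inner)
        else:
            self.csp4 = C3(rng, c5, c5, n_rep)

        # neck: top lateral, optionally through CFFI
        if config.use_cffi:
            self.cffi = CFFI(c5, c(768), rng,
                             InvolutionConfig(kernel_size=1, groups=1))
            self.lat5 = Conv(rng, self.cffi.out_channels, c4, k=1)
        else:
            self.cffi = None
            self.lat5 = Conv(rng, c5, c4, k=1)
        self.neck_td1 = C3(rng, c4 + c4, c4, n_rep)      # stride 16, top-down
        self.lat4 = Conv(rng, c4, c3, k=1)
        self.neck_td2 = C3(rng, c3 + c3, c3, n_rep)      # stride 8
        self.down_bu1 = Conv(rng, c3, c3, k=3, stride=2)
        self.neck_bu1 = C3(rng, c3 + c3, c4, n_rep)      # stride 16, bottom-up
        self.down_bu2 = Conv(rng, c4, c4, k=3, stride=2)
        self.neck_bu2 = C3(rng, c4 + c4, c5, n_rep)      # stride 32

        head_ch = [c3, c4, c5]
        if config.use_asff:
            self.asff = [
                ASFFHead(head_ch, list(config.strides), i, rng,
                         config.interpolation)
                for i in range(3)
            ]
        else:
            self.asff = None
        out_ch = config.n_anchors * config.n_outputs
        self.heads = [Conv(rng, hc, out_ch, k=1, act=False) for hc in head_ch]

    # ---------------------------------------------------------------- passes
    def forward(self, x: Tensor) -> list[Tensor]:
        """Input (N, 3, S, S) in [0,1] -> three prediction tensors with
        shapes (N, na*(5+nc), S/8, S/8), (..., S/16, ...), (..., S/32, ...)."""
        y = self.stem(x)
        y = self.csp1(self.down1(y))
        p3 = self.csp2(self.down2(y))
        p4 = self.csp3(self.down3(p3))
        c5 = self.csp4(self.down4(p4))

        top = self.cffi(c5) if self.cffi is not None else c5
        lat = self.lat5(top)
        t = self.neck_td1(ad.concat([ad.upsample_nearest(lat, 2), p4], axis=1))
        lat4 = self.lat4(t)
        n3 = self.neck_td2(ad.concat([ad.upsample_nearest(lat4, 2), p3], axis=1))
        n4 = self.neck_bu1(ad.concat([self.down_bu1(n3), lat4], axis=1))
        n5 = self.neck_bu2(ad.concat([self.down_bu2(n4), lat], axis=1))

        feats = [n3, n4, n5]
        if self.asff is not None:
            feats = [head(feats) for head in self.asff]
        return [h(f) for h, f in zip(self.heads, feats)]

    # --------------------------------------------------------- persistence
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(arrays):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = a.astype(ad.DTYPE)


def build_model(config: ModelConfig) -> Detector:
    """Construct the detector; deterministic given ``config.seed``."""
    return Detector(config)


def save_checkpoint(path, model: Detector) -> None:
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, config=np.array([repr(asdict(model.config))]), **arrays)


def load_checkpoint(path) -> Detector:
    import ast
    data = np.load(path, allow_pickle=False)
    cfg_dict = ast.literal_eval(str(data["config"][0]))
    cfg_dict["anchors"] = tuple(tuple(tuple(a) for a in lvl)
                                for lvl in cfg_dict["anchors"])
    cfg_dict["strides"] = tuple(cfg_dict["strides"])
    model = build_model(ModelConfig(**cfg_dict))
    n = len(model.parameters())
    model.load_state_arrays([data[f"p{i}"] for i in range(n)])
    return model


# ------------------------------------------------------------------- decode
def _sigmoid(x: np.ndarray) -> np.ndarray:
    return ad.stable_sigmoid(np.asarray(x, dtype=np.float64))


def decode(predictions: list[Tensor | np.ndarray], config: ModelConfig,
           image_ids: list[str] | None = None) -> list[DetectionSet]:
    """Raw prediction tensors -> pre-NMS detections in pixel coordinates.

    Per anchor cell: center = (2*sig(tx) - 0.5 + grid) * stride, size =
    (2*sig(twh))^2 * anchor, confidence = sig(obj) * sig(cls).  With all-zero
    logits every box sits at its cell center at anchor size with confidence
    0.25.
    """
    na, no = config.n_anchors, config.n_outputs
    batch = (predictions[0].data if isinstance(predictions[0], Tensor)
             else predictions[0]).shape[0]
    out = []
    for b in range(batch):
        boxes = []
        for level, pred in enumerate(predictions):
            p = pred.data if isinstance(pred, Tensor) else pred
            _, _, h, w = p.shape
            stride = config.strides[level]
            p = p[b].reshape(na, no, h, w)
            gx, gy = np.meshgrid(np.arange(w), np.arange(h))
            for a in range(na):
                aw, ah = config.anchors[level][a]
                s = _sigmoid(p[a])
                cx = (2 * s[0] - 0.5 + gx) * stride
                cy = (2 * s[1] - 0.5 + gy) * stride
                bw = (2 * s[2]) ** 2 * aw
                bh = (2 * s[3]) ** 2 * ah
                obj = s[4]
                cls_probs = s[5:]
                cls_id = cls_probs.argmax(axis=0)
                conf = obj * np.take_along_axis(
                    cls_probs, cls_id[None], axis=0)[0]
                for i in range(h):
                    for j in range(w):
                        x1 = float(cx[i, j] - bw[i, j] / 2)
                        y1 = float(cy[i, j] - bh[i, j] / 2)
                        x2 = float(cx[i, j] + bw[i, j] / 2)
                        y2 = float(cy[i, j] + bh[i, j] / 2)
                        if x2 <= x1 or y2 <= y1:  # size underflow
                            continue
                        boxes.append((int(cls_id[i, j]), float(conf[i, j]),
                                      x1, y1, x2, y2))
        out.append(DetectionSet(
            boxes=boxes,
            image_id=image_ids[b] if image_ids else f"image-{b}"))
    return out


def nms(dets: DetectionSet, iou_threshold: float = 0.45,
        conf_threshold: float = 0.1) -> DetectionSet:
    """Greedy class-wise non-maximum suppression.

    Keeps the highest-confidence box, removes same-class boxes overlapping it
    beyond ``iou_threshold``, and repeats; boxes below ``conf_threshold`` are
    dropped first.  Output is sorted by descending confidence.
    """
    from .metrics import iou as iou_fn

    kept: list[tuple] = []
    candidates = sorted(
        (b for b in dets.boxes if b[1] >= conf_threshold),
        key=lambda b: -b[1])
    suppressed = [False] * len(candidates)
    for i, box in enumerate(candidates):
        if suppressed[i]:
            continue
        kept.append(box)
        for j in range(i + 1, len(candidates)):
            if suppressed[j] or candidates[j][0] != box[0]:
                continue
            if iou_fn(box[2:], candidates[j][2:]) > iou_threshold:
                suppressed[j] = True
    return DetectionSet(boxes=kept, image_id=dets.image_id)


# --------------------------------------------------------------------- loss
def _ciou(pred: dict, tgt: np.ndarray) -> Tensor:
    """Complete IoU between decoded predicted boxes and target boxes, both as
    (cx, cy, w, h) in grid units.  ``pred`` holds Tensors, ``tgt`` is (M, 4)."""
    px, py, pw, ph = pred["x"], pred["y"], pred["w"], pred["h"]
    tx = Tensor(tgt[:, 0]); ty = Tensor(tgt[:, 1])
    tw = Tensor(tgt[:, 2]); th = Tensor(tgt[:, 3])
    px1, px2 = px - pw * 0.5, px + pw * 0.5
    py1, py2 = py - ph * 0.5, py + ph * 0.5
    tx1, tx2 = tx - tw * 0.5, tx + tw * 0.5
    ty1, ty2 = ty - th * 0.5, ty + th * 0.5
    iw = (px2.minimum(tx2) - px1.maximum(tx1)).relu()
    ih = (py2.minimum(ty2) - py1.maximum(ty1)).relu()
    inter = iw * ih
    union = pw * ph + tw * th - inter + 1e-7
    iou = inter / union
    # enclosing box diagonal
    cw = px2.maximum(tx2) - px1.minimum(tx1)
    chh = py2.maximum(ty2) - py1.minimum(ty1)
    c2 = cw * cw + chh * chh + 1e-7
    rho2 = (px - tx) ** 2 + (py - ty) ** 2
    v = (4.0 / math.pi ** 2) * ((tw / (th + 1e-7)).arctan()
                                - (pw / (ph + 1e-7)).arctan()) ** 2
    alpha = Tensor(v.data / (1.0 - iou.data + v.data + 1e-7))  # detached
    return iou - rho2 / c2 - v * alpha


def assign_targets(truth_boxes, config: ModelConfig):
    """YOLO anchor assignment: a ground-truth box is matched to every anchor
    whose w/h ratio is within a factor of 4, on its level's containing cell
    and the two nearest neighbour cells.

    ``truth_boxes``: list over batch of lists of (cls, cx, cy, w, h) in
    pixels.  Returns per level a list of (batch_i, anchor_a, cell_j, cell_i,
    tx, ty, tw, th, cls) tuples with targets in grid units.
    """
    out = [[] for _ in config.strides]
    for bi, boxes in enumerate(truth_boxes):
        for cls, cx, cy, w, h in boxes:
            for level, stride in enumerate(config.strides):
                g = config.input_size // stride
                gx, gy = cx / stride, cy / stride
                gw, gh = w / stride, h / stride
                for a, (aw, ah) in enumerate(config.anchors[level]):
                    rw, rh = w / aw, h / ah
                    if max(rw, 1 / rw) >= 4 or max(rh, 1 / rh) >= 4:
                        continue
                    ci, cj = int(gy), int(gx)
                    cells = {(ci, cj)}
                    fx, fy = gx - cj, gy - ci
                    if fx < 0.5 and cj > 0:
                        cells.add((ci, cj - 1))
                    elif fx >= 0.5 and cj < g - 1:
                        cells.add((ci, cj + 1))
                    if fy < 0.5 and ci > 0:
                        cells.add((ci - 1, cj))
                    elif fy >= 0.5 and ci < g - 1:
                        cells.add((ci + 1, cj))
                    for (ti, tj) in cells:
                        if 0 <= ti < g and 0 <= tj < g:
                            out[level].append(
                                (bi, a, ti, tj, gx, gy, gw, gh, int(cls)))
    return out


# Desk-scale balance: the box term carries full weight so localization keeps
# pace with objectness on short CPU runs.
LOSS_GAINS = {"box": 1.0, "obj": 1.0, "cls": 0.5}
OBJ_BALANCE = (4.0, 1.0, 0.4)   # more weight on the fine level


def detection_loss(predictions: list[Tensor], truth_boxes,
                   config: ModelConfig) -> dict[str, Tensor]:
    """Composite detection loss.

    Components: box = mean(1 - CIoU) over assigned anchors; obj = BCE of
    objectness logits against the assignment indicator (balanced per level);
    cls = BCE of class logits at assigned anchors.  With no ground truth the
    box/cls terms are zero and obj pushes all objectness toward zero.
    """
    na, no = config.n_anchors, config.n_outputs
    targets = assign_targets(truth_boxes, config)
    box_terms, cls_terms, obj_terms = [], [], []
    for level, pred in enumerate(predictions):
        n, _, h, w = pred.shape
        p = pred.reshape(n, na, no, h, w)
        obj_target = np.zeros((n, na, h, w), dtype=ad.DTYPE)
        t = targets[level]
        if t:
            bi = [x[0] for x in t]; ai = [x[1] for x in t]
            ci = [x[2] for x in t]; cj = [x[3] for x in t]
            tgt = np.array([x[4:8] for x in t], dtype=np.float64)
            cls = np.array([x[8] for x in t])
            obj_target[bi, ai, ci, cj] = 1.0

            sel = p[bi, ai, :, ci, cj]            # (M, no)
            sx = sel[:, 0].sigmoid() * 2.0 - 0.5 + Tensor(np.array(cj, dtype=ad.DTYPE))
            sy = sel[:, 1].sigmoid() * 2.0 - 0.5 + Tensor(np.array(ci, dtype=ad.DTYPE))
            anchors = np.array(config.anchors[level], dtype=ad.DTYPE)
            aw = Tensor(anchors[ai, 0] / config.strides[level])
            ah = Tensor(anchors[ai, 1] / config.strides[level])
            sw = (sel[:, 2].sigmoid() * 2.0) ** 2 * aw
            sh = (sel[:, 3].sigmoid() * 2.0) ** 2 * ah
            ciou = _ciou({"x": sx, "y": sy, "w": sw, "h": sh}, tgt)
            box_terms.append((1.0 - ciou).mean())

            cls_target = np.zeros((len(t), config.n_classes), dtype=ad.DTYPE)
            cls_target[np.arange(len(t)), cls] = 1.0
            cls_terms.append(ad.bce_with_logits(sel[:, 5:], cls_target))

        obj_logits = p[:, :, 4]
        obj_terms.append(
            ad.bce_with_logits(obj_logits, obj_target) * OBJ_BALANCE[level])

    zero = Tensor(np.zeros(()))
    box = sum(box_terms, zero) * (1.0 / max(len(box_terms), 1))
    cls_l = sum(cls_terms, zero) * (1.0 / max(len(cls_terms), 1))
    obj = sum(obj_terms, zero) * (1.0 / len(obj_terms))
    total = box * LOSS_GAINS["box"] + obj * LOSS_GAINS["obj"] \
        + cls_l * LOSS_GAINS["cls"]
    return {"box": box, "obj": obj, "cls": cls_l, "total": total}


# ----------------------------------------------------------------- training
def image_to_input(img: AnnotatedImage, input_size: int) -> tuple[np.ndarray, list]:
    """Resize (nearest) an annotated image to the square network input and
    return (3, S, S) float input in [0,1] plus pixel-space truth boxes."""
    h, w = img.pixels.shape[:2]
    s = input_size
    ri = np.clip((np.arange(s) + 0.5) * h / s, 0, h - 1).astype(int)
    ci = np.clip((np.arange(s) + 0.5) * w / s, 0, w - 1).astype(int)
    resized = img.pixels[ri][:, ci]
    x = resized.astype(ad.DTYPE).transpose(2, 0, 1) / 255.0
    boxes = [(cls, cx * s, cy * s, bw * s, bh * s)
             for cls, cx, cy, bw, bh in img.boxes]
    return x, boxes


def predict_image(model: Detector, img: AnnotatedImage,
                  conf_threshold: float = 0.1,
                  iou_threshold: float = 0.45) -> DetectionSet:
    """Forward + decode + NMS for one image; boxes in network-input pixels."""
    x, _ = image_to_input(img, model.config.input_size)
    preds = model.forward(Tensor(x[None]))
    dets = decode(preds, model.config, image_ids=[img.image_id])[0]
    return nms(dets, iou_threshold=iou_threshold, conf_threshold=conf_threshold)


def evaluate_model(model: Detector, images: list[AnnotatedImage],
                   conf_threshold: float = 0.1) -> "MetricsReport":
    """mAP report of the model on a list of annotated images."""
    from .metrics import evaluate

    dets, truths = {}, {}
    s = model.config.input_size
    for img in images:
        d = predict_image(model, img, conf_threshold=conf_threshold)
        dets[img.image_id] = [(c, conf, x1, y1, x2, y2)
                              for c, conf, x1, y1, x2, y2 in d.boxes]
        _, boxes = image_to_input(img, s)
        truths[img.image_id] = [
            (cls, cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
            for cls, cx, cy, w, h in boxes]
    return evaluate(dets, truths, classes=tuple(range(model.config.n_classes)))


def train(model: Detector, images: list[AnnotatedImage],
          epochs: int = 30, batch_size: int = 8, lr: float = 0.05,
          momentum: float = 0.9, weight_decay: float = 0.0,
          seed: int = 0, val_images: list[AnnotatedImage] | None = None,
          val_every: int = 0, max_grad_norm: float = 5.0) -> TrainState:
    """SGD training loop; deterministic given ``seed`` on one thread.

    Gradients are clipped to a global norm of ``max_grad_norm`` before each
    step; the attention blocks occasionally produce sharp gradients early in
    training and clipping keeps a single learning rate usable across the
    whole ablation grid.

    Logs per-epoch mean loss components; when ``val_images`` is given,
    validation mAP@0.5 is computed every ``val_every`` epochs (and always at
    the last epoch).  Raises :class:`NonFiniteLossError` naming the first
    non-finite component.
    """
    if not images:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(seed)
    opt = ad.SGD(model.parameters(), lr=lr, momentum=momentum,
                 weight_decay=weight_decay)
    state = TrainState(seed=seed, hyperparameters={
        "epochs": epochs, "batch_size": batch_size, "lr": lr,
        "momentum": momentum, "weight_decay": weight_decay})
    cache = [image_to_input(img, model.config.input_size) for img in images]

    for epoch in range(epochs):
        order = rng.permutation(len(cache))
        sums = {"box": 0.0, "obj": 0.0, "cls": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            xb = Tensor(np.stack([cache[i][0] for i in idx]))
            boxes = [cache[i][1] for i in idx]
            preds = model.forward(xb)
            losses = detection_loss(preds, boxes, model.config)
            for name in ("box", "obj", "cls", "total"):
                v = float(losses[name].data)
                if not np.isfinite(v):
                    raise NonFiniteLossError(
                        f"non-finite {name} loss at epoch {epoch}")
                sums[name] += v
            opt.zero_grad()
            losses["total"].backward()
            if max_grad_norm:
                total_sq = sum(float((p.grad ** 2).sum())
                               for p in model.parameters()
                               if p.grad is not None)
                norm = math.sqrt(total_sq)
                if norm > max_grad_norm:
                    scale = max_grad_norm / norm
                    for p in model.parameters():
                        if p.grad is not None:
                            p.grad *= np.float32(scale)
            opt.step()
            n_batches += 1
        state.epochs.append(epoch)
        state.box_loss.append(sums["box"] / n_batches)
        state.obj_loss.append(sums["obj"] / n_batches)
        state.cls_loss.append(sums["cls"] / n_batches)
        state.total_loss.append(sums["total"] / n_batches)
        if val_images and (epoch == epochs - 1
                           or (val_every and (epoch + 1) % val_every == 0)):
            state.val_map50.append(evaluate_model(model, val_images).map50)
        else:
            state.val_map50.append(None)
    return state
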