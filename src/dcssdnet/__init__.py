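"""DC-SSDNet: densely connected single-shot multibox detector for polyps.

A compact DenseNet-46 backbone (stem block + six dense/transition
phases) feeding a six-level multiscale feature pyramid with SSD-style
class and box prediction heads, together with the training, data, and
evaluation pipeline around it.
"""

from .backbone import (ArchConfig, DenseBlockSpec, FeatureMapShape,
                       assemble_backbone, build_dense_block, build_stem,
                       build_transition_block, infer_feature_shapes)
from .boxes import (DefaultBoxSet, MatchResult, decode_boxes, encode_boxes,
                    generate_default_boxes, iou, iou_matrix, match_targets,
                    nms)
from .data import (AnnotatedFrame, SyntheticSceneSpec,
                   generate_synthetic_dataset, kfold, read_voc_annotation,
                   roi_center_crop, split_dataset, transform_sample,
                   write_voc_annotation)
from .evaluation import (ConfusionCounts, EvalResult, average_precision,
                         evaluate_detections, f1_score, match_detections,
                         measure_fps, mean_average_precision,
                         precision_recall_f1)
from .loss import LossBreakdown, LossConfig, hard_negative_mine, multibox_loss
from .pyramid import (DCSSDNet, PyramidSpec, RawPredictions, attach_pyramid,
                      build_predictors)
from .train import (TrainConfig, TrainLog, load_checkpoint, lr_at_epoch,
                    normalize_images, save_checkpoint, train_model)

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]
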