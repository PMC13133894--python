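{
  "table6": {
    "description": "Binary clubbing-vs-normal confusion matrix (3,700 test images).",
    "metric_table": "All four published metrics (accuracy 95.46, precision 95.94, recall 95.45, F1 95.69, percent) recompute exactly from this matrix; precision/recall/F1 refer to the clubbing class.",
    "inconsistent_cells": {}
  },
  "table8": {
    "description": "Three-landmark localization confusion matrix (1,956 images per landmark).",
    "metric_table": "Recalls and precisions recompute from this matrix; a few published cells are truncated rather than rounded.",
    "inconsistent_cells": {
      "nail_matrix.precision": {"printed": 95.47, "recomputed": 95.48},
      "nail_matrix.f1": {"printed": 93.55, "recomputed": 93.56},
      "proximal_nail_fold.f1": {"printed": 94.48, "recomputed": 94.49},
      "average.precision": {"printed": 94.59, "recomputed": 94.60}
    }
  },
  "table10": {
    "description": "Landmark localization confusion matrix after augmentation-based training.",
    "metric_table": "All published cells recompute from this matrix except one truncated F1 cell.",
    "inconsistent_cells": {
      "nail_plate.f1": {"printed": 96.16, "recomputed": 96.17}
    }
  },
  "table12": {
    "description": "Integrated four-level severity confusion matrix (3,700 images; 1,744 normal, 652 per clubbing grade).",
    "metric_table": "Overall accuracy (94.7), severe recall (95.7) and mild F1 (89.8) recompute exactly. The cells below do not recompute from the matrix and are excluded from verification.",
    "inconsistent_cells": {
      "normal.recall": {"printed": 97.0, "recomputed": 97.1},
      "mild.precision": {"printed": 88.0, "recomputed": 87.9},
      "mild.recall": {"printed": 91.6, "recomputed": 91.7},
      "moderate.precision": {"printed": 90.7, "recomputed": 89.1},
      "moderate.recall": {"printed": 86.3, "recomputed": 90.2},
      "severe.precision": {"printed": 96.2, "recomputed": 96.3},
      "macro.f1": {"printed": 93.0, "recomputed": 93.4, "note": "published macro F1 appears to average the published (partly inconsistent) per-class cells"}
    }
  }
}
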