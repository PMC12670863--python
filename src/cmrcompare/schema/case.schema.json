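{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Case annotation interchange format",
  "description": "One reader's contour annotations for one case of one CMR sequence. Contour points are continuous 0-based pixel coordinates [col, row]; physical sizes follow from geometry.",
  "type": "object",
  "required": ["case_id", "reader_id", "sequence", "geometry", "slices"],
  "properties": {
    "case_id": {"type": "string"},
    "reader_id": {"type": "string"},
    "sequence": {
      "enum": ["sax_cine", "sax_t1", "sax_t2", "sax_lge", "lax_2cv", "lax_4cv"]
    },
    "geometry": {
      "type": "object",
      "required": ["spacing_row", "spacing_col", "slice_thickness"],
      "properties": {
        "spacing_row": {"type": "number", "exclusiveMinimum": 0},
        "spacing_col": {"type": "number", "exclusiveMinimum": 0},
        "slice_thickness": {"type": "number", "exclusiveMinimum": 0},
        "slice_gap": {"type": "number", "minimum": 0, "default": 0}
      }
    },
    "slices": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["slice_index", "phase"],
        "properties": {
          "slice_index": {"type": "integer", "minimum": 0},
          "phase": {"enum": ["ES", "ED", "single"]},
          "contours": {
            "type": "object",
            "propertyNames": {
              "enum": ["lv_endo", "lv_epi", "rv_endo", "la", "ra", "scar", "papmu", "refpoint"]
            },
            "additionalProperties": {
              "type": "array",
              "description": "list of polygons (a list of length > 1 encodes a fragmented segmentation); each polygon is a list of [col, row] vertices, implicitly closed; refpoint carries exactly one single-point 'polygon'",
              "items": {
                "type": "array",
                "items": {
                  "type": "array",
                  "prefixItems": [{"type": "number"}, {"type": "number"}],
                  "minItems": 2,
                  "maxItems": 2
                }
              }
            }
          },
          "value_map": {
            "type": "object",
            "required": ["shape", "values"],
            "properties": {
              "shape": {
                "type": "array",
                "prefixItems": [{"type": "integer"}, {"type": "integer"}],
                "minItems": 2,
                "maxItems": 2
              },
              "values": {
                "type": "array",
                "items": {"type": "number"},
                "description": "row-major voxel values (ms); voxel (i,j) centred at (row=i, col=j)"
              }
            }
          }
        }
      }
    }
  }
}
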