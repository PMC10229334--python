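{
 "$defs": {
  "CerebellarFindings": {
   "additionalProperties": false,
   "description": "Cerebellar ataxia grade plus the qualifying signs the rubric names.",
   "properties": {
    "severity": {
     "default": "none",
     "enum": [
      "none",
      "mild",
      "moderate",
      "severe"
     ],
     "title": "Severity",
     "type": "string"
    },
    "truncal_sway": {
     "default": false,
     "title": "Truncal Sway",
     "type": "boolean"
    },
    "hypermetria": {
     "default": false,
     "title": "Hypermetria",
     "type": "boolean"
    },
    "tremors": {
     "default": false,
     "title": "Tremors",
     "type": "boolean"
    }
   },
   "title": "CerebellarFindings",
   "type": "object"
  },
  "VisionFindings": {
   "additionalProperties": false,
   "description": "Menace-response status per eye, with impaired vision where reduced/absent.",
   "properties": {
    "left": {
     "default": "normal",
     "enum": [
      "normal",
      "reduced_with_impaired_vision",
      "absent_with_impaired_vision"
     ],
     "title": "Left",
     "type": "string"
    },
    "right": {
     "default": "normal",
     "enum": [
      "normal",
      "reduced_with_impaired_vision",
      "absent_with_impaired_vision"
     ],
     "title": "Right",
     "type": "string"
    }
   },
   "title": "VisionFindings",
   "type": "object"
  }
 },
 "additionalProperties": false,
 "description": "One neurological examination of one dog by one assessor.\n\nField vocabulary follows the clinical-sign inventory of MUO presentations:\nproprioceptive deficits, obtundation, ataxia, visual deficits, head tilt,\nseizures, paresis, compulsive circling, hyperesthesia, behaviour changes,\npathological nystagmus, hypermetria, head turn, cranial-nerve dysfunction\nand tremors. ``hyperesthesia`` and ``proprioceptive_deficits`` are the two\nbinary items used only by the 9-item pilot scale.",
 "properties": {
  "subject_id": {
   "title": "Subject Id",
   "type": "string"
  },
  "ambulatory": {
   "default": "normal",
   "enum": [
    "normal",
    "ambulatory_mild_deficit",
    "ambulatory_frequent_falling",
    "nonambulatory"
   ],
   "title": "Ambulatory",
   "type": "string"
  },
  "cerebral_signs": {
   "items": {
    "enum": [
     "disorientation",
     "obtundation",
     "behavior_change",
     "stupor",
     "coma",
     "compulsive_circling",
     "head_pressing"
    ],
    "type": "string"
   },
   "title": "Cerebral Signs",
   "type": "array",
   "uniqueItems": true
  },
  "cerebellar": {
   "$ref": "#/$defs/CerebellarFindings"
  },
  "brainstem_signs": {
   "items": {
    "enum": [
     "facial_nerve_dysfunction",
     "positional_pathological_nystagmus",
     "trigeminal_dysfunction",
     "hypoglossal_dysfunction",
     "persistent_pathological_nystagmus",
     "dysphagia",
     "laryngeal_dysfunction"
    ],
    "type": "string"
   },
   "title": "Brainstem Signs",
   "type": "array",
   "uniqueItems": true
  },
  "vision": {
   "$ref": "#/$defs/VisionFindings"
  },
  "posture": {
   "items": {
    "enum": [
     "head_tilt",
     "head_turn",
     "pleurothotonus",
     "decerebellate_rigidity",
     "decerebrate_rigidity"
    ],
    "type": "string"
   },
   "title": "Posture",
   "type": "array",
   "uniqueItems": true
  },
  "seizure_history_7d": {
   "default": "none",
   "enum": [
    "none",
    "controlled",
    "cluster_or_refractory",
    "status_epilepticus"
   ],
   "title": "Seizure History 7D",
   "type": "string"
  },
  "hyperesthesia": {
   "default": false,
   "title": "Hyperesthesia",
   "type": "boolean"
  },
  "proprioceptive_deficits": {
   "default": false,
   "title": "Proprioceptive Deficits",
   "type": "boolean"
  },
  "in_status_epilepticus": {
   "default": false,
   "title": "In Status Epilepticus",
   "type": "boolean"
  }
 },
 "required": [
  "subject_id",
  "ambulatory",
  "cerebral_signs",
  "cerebellar",
  "brainstem_signs",
  "vision",
  "posture",
  "seizure_history_7d"
 ],
 "title": "NeuroExamRecord",
 "type": "object"
}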