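[
  {"scale_id": "HGS", "item_id": "ears", "label": "Stiffly backward ears", "min_score": 0, "max_score": 2, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "HGS", "item_id": "orb", "label": "Orbital tightening", "min_score": 0, "max_score": 2, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "HGS", "item_id": "ten", "label": "Tension above the eye area", "min_score": 0, "max_score": 2, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "HGS", "item_id": "chew", "label": "Prominent strained chewing muscles", "min_score": 0, "max_score": 2, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "HGS", "item_id": "mouth", "label": "Mouth strained and pronounced chin", "min_score": 0, "max_score": 2, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "HGS", "item_id": "nost", "label": "Strained nostrils and flattening of the profile", "min_score": 0, "max_score": 2, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "EQUUS_FAP", "item_id": "head", "label": "Head", "min_score": 0, "max_score": 2, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "EQUUS_FAP", "item_id": "eye", "label": "Eyelids", "min_score": 0, "max_score": 2, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "EQUUS_FAP", "item_id": "focus", "label": "Focus", "min_score": 0, "max_score": 2, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "EQUUS_FAP", "item_id": "nost", "label": "Nostrils", "min_score": 0, "max_score": 2, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "EQUUS_FAP", "item_id": "mouth", "label": "Corners mouth/lips", "min_score": 0, "max_score": 2, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "EQUUS_FAP", "item_id": "tone", "label": "Muscle tone head", "min_score": 0, "max_score": 2, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "EQUUS_FAP", "item_id": "fleya", "label": "Flehmen and/or yawning", "min_score": 0, "max_score": 2, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "EQUUS_FAP", "item_id": "teeth", "label": "Teeth grinding and/or moaning", "min_score": 0, "max_score": 2, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "EQUUS_FAP", "item_id": "ears", "label": "Ears", "min_score": 0, "max_score": 2, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "EPS", "item_id": "pf", "label": "Pain face", "min_score": 0, "max_score": 4, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "EPS", "item_id": "gross", "label": "Gross pain behavior", "min_score": 0, "max_score": 4, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "EPS", "item_id": "act", "label": "Activity", "min_score": 0, "max_score": 4, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "EPS", "item_id": "loc", "label": "Location in the stall", "min_score": 0, "max_score": 4, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "EPS", "item_id": "pos", "label": "Posture/weight bearing", "min_score": 0, "max_score": 4, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "EPS", "item_id": "head", "label": "Head position", "min_score": 0, "max_score": 4, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "EPS", "item_id": "att", "label": "Attention towards painful area", "min_score": 0, "max_score": 4, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "EPS", "item_id": "int", "label": "Interactive behavior", "min_score": 0, "max_score": 4, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "EPS", "item_id": "food", "label": "Response to food", "min_score": 0, "max_score": 4, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "CPS", "item_id": "kick", "label": "Kicking abdomen", "min_score": 0, "max_score": 3, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "CPS", "item_id": "paw", "label": "Pawing on the floor", "min_score": 0, "max_score": 3, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "CPS", "item_id": "head", "label": "Head movement", "min_score": 0, "max_score": 3, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "CPS", "item_id": "app", "label": "Appearance", "min_score": 0, "max_score": 3, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "CPS", "item_id": "pos", "label": "Posture", "min_score": 0, "max_score": 3, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "CPS", "item_id": "app2", "label": "Appetite", "min_score": 0, "max_score": 3, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "CPS", "item_id": "sweat", "label": "Sweating", "min_score": 0, "max_score": 3, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "CPS", "item_id": "int", "label": "Interactive behavior", "min_score": 0, "max_score": 3, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "CPS", "item_id": "palp", "label": "Response to palpation of painful area", "min_score": 0, "max_score": 3, "is_physiological": false, "is_behavioral": true},
  {"scale_id": "CPS", "item_id": "temp", "label": "Rectal temperature", "min_score": 0, "max_score": 3, "is_physiological": true, "is_behavioral": false},
  {"scale_id": "CPS", "item_id": "hr", "label": "Heart rate", "min_score": 0, "max_score": 3, "is_physiological": true, "is_behavioral": false},
  {"scale_id": "CPS", "item_id": "rr", "label": "Respiratory rate", "min_score": 0, "max_score": 3, "is_physiological": true, "is_behavioral": false},
  {"scale_id": "CPS", "item_id": "digest", "label": "Digestive sounds", "min_score": 0, "max_score": 3, "is_physiological": true, "is_behavioral": false}
]
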