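{
 "$defs": {
  "AuditRecord": {
   "properties": {
    "mature_id": {
     "title": "Mature Id",
     "type": "string"
    },
    "max_cpm": {
     "minimum": 0,
     "title": "Max Cpm",
     "type": "number"
    },
    "argmax_sample": {
     "title": "Argmax Sample",
     "type": "string"
    },
    "argmax_dataset": {
     "title": "Argmax Dataset",
     "type": "string"
    },
    "bin": {
     "title": "Bin",
     "type": "string"
    },
    "not_detected": {
     "title": "Not Detected",
     "type": "boolean"
    }
   },
   "required": [
    "mature_id",
    "max_cpm",
    "argmax_sample",
    "argmax_dataset",
    "bin",
    "not_detected"
   ],
   "title": "AuditRecord",
   "type": "object"
  }
 },
 "properties": {
  "schema_version": {
   "const": 1,
   "title": "Schema Version",
   "type": "integer"
  },
  "manifest": {
   "anyOf": [
    {
     "type": "string"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Manifest"
  },
  "records": {
   "items": {
    "$ref": "#/$defs/AuditRecord"
   },
   "title": "Records",
   "type": "array"
  }
 },
 "required": [
  "schema_version",
  "records"
 ],
 "title": "miraudit audit report",
 "type": "object",
 "$schema": "https://json-schema.org/draft/2020-12/schema"
}
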