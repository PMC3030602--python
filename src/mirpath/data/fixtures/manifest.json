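{
 "files": {
  "table2.tsv": "cc77aae3139b503db87a6aa60fc1539e1f511c6c7ded122c2af3e0e727cdddd5",
  "table3.tsv": "67c0e3807fe3eddd2803254b93da7344252def4db8a2492ddb28355e29c4de06",
  "table4.tsv": "3c5bd67ff6622661d39c01222fb05ca6c51ee4031a8ad81d92df0f08bafde351",
  "table5.tsv": "ffb6c5108c74ebef663745c0993c3a08106769ba4df398f020c312b1d210125c"
 },
 "notes": {
  "lt_sentence_count": 67,
  "mir146b_it_fi": {
   "table2": 1.55,
   "table5": 1.56
  },
  "mir483_lt_fi": {
   "table2": 115.8,
   "table3": 116.16
  },
  "table2_rows": {
   "IT": 26,
   "LT": 69,
   "ST": 20
  }
 }
}
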