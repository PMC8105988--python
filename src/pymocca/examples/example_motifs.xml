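<?xml version="1.0" encoding="UTF-8"?>
<!-- Example IUPAC motif set (synthetic, for demonstration and testing only).
     Patterns are shaped like classic PRE-associated factor binding motifs
     but are not a published motif collection. -->
<motifs>
  <motif name="GAF" iupac="GAGAG"/>
  <motif name="PHO" iupac="GCCAT"/>
  <motif name="ZESTE" iupac="YGAGYG"/>
  <motif name="EN1" iupac="GSNMACGCCCC" mismatches="1"/>
  <motif name="GTGT" iupac="GTGT"/>
</motifs>
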