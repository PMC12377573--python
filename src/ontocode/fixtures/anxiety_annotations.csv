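item_id,coder_id,text,codes
004,GS,"Anxiety and depression",48694002|35489007
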