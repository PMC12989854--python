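(((T01:0.4934700331,((T02:0.1591505769,T03:0.1591505769):0.2687741573,T04:0.4279247342):0.0655452989):0.4905551397,((T05:0.1906727007,T06:0.1906727007):0.6112960966,T07:0.8019687973):0.1820563755):1.068930535,(T08:1.3419098607,(T09:0.4017879483,T10:0.4017879483):0.9401219125):0.7110458471);
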