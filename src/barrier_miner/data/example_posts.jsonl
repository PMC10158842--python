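{"post_id": "ex01", "subreddit": "Methadone", "created": "2020-03-14T12:00:00+00:00", "kind": "submission", "parent_id": null, "text": "I really do not exactly want to broadcast to the world that I'm on methadone. Not because I'm embarrassed but stigma sucks"}
{"post_id": "ex02", "subreddit": "suboxone", "created": "2020-05-02T09:30:00+00:00", "kind": "submission", "parent_id": null, "text": "My insurance is always either denying my script completely or asking for prior auths every other month. Please help me."}
{"post_id": "ex03", "subreddit": "suboxone", "created": "2019-11-20T18:05:00+00:00", "kind": "comment", "parent_id": "ex02", "text": "I do not have a q script because I do not have insurance."}
{"post_id": "ex04", "subreddit": "naltrexone", "created": "2021-01-08T22:40:00+00:00", "kind": "submission", "parent_id": null, "text": "The biggest issue with this medication is the cost. It's $5,000 at least and insurance does not want to pay."}
{"post_id": "ex05", "subreddit": "suboxone", "created": "2018-07-19T14:10:00+00:00", "kind": "submission", "parent_id": null, "text": "I worry about this all the time. That my doctor will die, and I will not find another who will take my insurance, or they'll gouge me for a $500 visit."}
{"post_id": "ex06", "subreddit": "suboxone", "created": "2019-02-23T16:55:00+00:00", "kind": "comment", "parent_id": "ex05", "text": "The only reason I switched from suboxone to tex is bc I lost my health insurance."}
{"post_id": "ex07", "subreddit": "Methadone", "created": "2020-09-30T11:25:00+00:00", "kind": "submission", "parent_id": null, "text": "Getting insurance to pay for a preauthorization was a nightmare."}
{"post_id": "ex08", "subreddit": "suboxone", "created": "2021-04-11T08:45:00+00:00", "kind": "submission", "parent_id": null, "text": "When only name brand strips were available, they would tell be it cannot be refilled because they do not have it in stock. people treat Suboxone users like full blown heroin addicts."}
{"post_id": "ex09", "subreddit": "Methadone", "created": "2017-10-05T20:15:00+00:00", "kind": "submission", "parent_id": null, "text": "Sad that access is so expensive."}
{"post_id": "ex10", "subreddit": "suboxone", "created": "2019-06-14T13:35:00+00:00", "kind": "submission", "parent_id": null, "text": "I hate that we get the label as bad people or stupid for choosing to be an addict."}
{"post_id": "ex11", "subreddit": "Methadone", "created": "2020-12-01T17:20:00+00:00", "kind": "submission", "parent_id": null, "text": "What I'd really like to see is less requirements for getting take home medications to start with."}
{"post_id": "ex12", "subreddit": "suboxone", "created": "2021-02-17T10:05:00+00:00", "kind": "submission", "parent_id": null, "text": "I am shocked that I got snubbed like this."}
{"post_id": "ex13", "subreddit": "naltrexone", "created": "2018-03-29T19:50:00+00:00", "kind": "submission", "parent_id": null, "text": "I was interested in a solution but I was too afraid to try it."}
{"post_id": "ex14", "subreddit": "Methadone", "created": "2021-07-22T15:40:00+00:00", "kind": "submission", "parent_id": null, "text": "I have felt frustrated with many aspects of being on it such as urinalysis, snarky pharmacists, the cost, and often stigma associated with taking this."}
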